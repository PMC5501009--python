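# Methods

`frproi` implements a single-trial, ROI-resolved fixation-related-potential
(FRP) pipeline for co-registered EEG and eye tracking, together with a
ground-truthed simulator of the guided visual-search / auditory n-back
paradigm it is designed for. This note documents the models, the defaults
and their rationale, the numerical choices, and what the synthetic test bed
does and does not establish about real data.

## The analysis model

**Gaze.** Raw gaze is recalibrated post hoc against task knowledge: during
guided viewing the eye is expected at the cued location, so a per-axis
quadratic regression maps raw to expected position, pairing each stimulus
interval's samples (after a 250 ms oculomotor lag) with the cue position.
Saccades are found with an Engbert-style velocity algorithm: velocity from a
5-sample central moving difference, per-axis thresholds at 6 robust
(median-estimator) standard deviations of the velocity distribution,
elliptic combination of axes, minimum saccade duration 20 ms, minimum
fixation duration 350 ms. When two saccades fall within 350 ms the smaller
is treated as corrective and absorbed, preserving only the fixation of the
larger saccade. Fixations are task-valid when they land within 3 degrees of
the active stimulus. Pupil size is summarized per condition relative to the
session mean (a ratio; invalid samples excluded).

**EEG conditioning.** Average-mastoid reference; zero-phase 4th-order
Butterworth filters (1 Hz high-pass before artifact screening, 50 Hz
low-pass after); polyphase resampling to f_s = 256 Hz. Broadband-noise
screening runs at the native 1,024 Hz, where the 90-120 Hz band sits
comfortably below Nyquist: 100 ms windows slide in 10 ms steps, the
channel-averaged band power of each window is compared with the session's
window distribution, and windows above mean + 3 SD are masked. The mask is
mapped onto the 256 Hz clock; masked stretches are excised from the record
before ICA and any fixation epoch touching a masked sample is dropped.

Fixation-locked epochs live on a fixed half-open grid [-300, 1000) ms:
samples k = -76 ... 255 at 256 Hz, i.e. 332 samples of which exactly 255
are strictly causal. This convention is load-bearing: every downstream
object (TF features, pointwise statistics) inherits it.

**Sources.** ICA is applied once to the whole cleaned session. The contract
is behavioral (independent sources mixed linearly must be recovered with a
low Amari index), and the reference implementation is FastICA with a
logcosh contrast; components are variance-sorted and sign-fixed so the
largest-magnitude entry of each scalp map is positive. Each component's
scalp map is then explained by one equivalent current dipole under a
spherical head model (infinite-homogeneous-medium point-dipole potential):
an 8 mm grid search, in which the optimal moment at each candidate location
is a linear least-squares fit, followed by Nelder-Mead refinement of the
location to 0.1 mm. The leadfield is re-expressed in the average-mastoid
reference so the fit space matches the data space. Components whose dipole
falls outside the brain sphere are excluded from all ROI analyses; no
residual-variance cutoff is applied (an optional threshold exists, default
off).

**Measure projection.** Each retained component i carries a measure M_i (an
FRP vector, a TF matrix, or a single-trial epoch) and a dipole at x_i.
Localization uncertainty is modeled as a spherical Gaussian of width
sigma = 12 mm centered at x_i, truncated at t*sigma with t = 3 and not
renormalized — truncation only removes the influence of distant dipoles
(at 36 mm the discarded Gaussian mass is below 1%). The expected measure at
a voxel is the density-weighted mean of the M_i, and an ROI's measure uses
density-mass weights w_{i,R} proportional to the dipole's mass inside the
ROI (normalized over components). Mass weighting, rather than an unweighted
voxel average, is chosen because it equals the density-overlap notion of a
component's contribution; the unweighted alternative differs only when the
density varies strongly across the ROI. The toy atlas places six spherical
ROIs (occipital, fusiform, bilateral temporal, parietal, cingulate,
frontal) on an 8 mm voxel grid inside the brain sphere.

**Time-frequency features.** A Torrence-Compo Morlet basis with central
frequency omega0 = 6 (the standard choice; it also makes the printed
1-128 Hz span come out right), 30 scales from s0 = 2/f_s with step 2^0.25,
unit-energy normalization per scale, FFT evaluation with zero-padding to
the next power of two and no cone-of-influence masking (edges are identical
across trials and carry no class information). Power is the squared
magnitude; the classifier sees frequencies at or below 32 Hz, flattened
frequency-major over all 332 epoch samples.

**Hierarchical classification.** Per ROI, ridge regression on standardized
TF features with the penalty set by the effective-degrees-of-freedom rule
df(lambda) = sum_j d_j^2/(d_j^2+lambda) = n_target (bisection on the
strictly decreasing df curve; with the paradigm's 10:1 class ratio this is
the "one target and ten non-targets per degree of freedom" heuristic). A
second-stage LDA fuses the six ROI scores. Both stages are fit inside one
stratified 5-fold cross-validation; the LDA is trained on the training
folds' resubstitution score vectors (the simplest reading of a single CV
scheme). Az is the rank-based area under the ROC with ties counted one
half, computed on pooled held-out scores; per-condition Az restricts those
pooled scores to a condition's trials rather than refitting per condition.
For interpretation, weights map to a Haufe-style forward model
A = Sigma_X W / var(s_hat) (the score covariance is a scalar for 1-D
scores); the activation magnitude summed over frequencies gives a temporal
profile whose causal center of mass is the discriminant latency.

**Comparators.** HDCA: the causal epoch is tiled into 8 equal windows,
channel means per window are reduced by shrinkage LDA, and a lightly
penalized logistic regression fuses the 8 scores. xDAWN+BLDA: spatial
filters from the generalized symmetric eigenproblem evoked-vs-total
covariance (evoked = training-fold mean target epoch), the 8 most
discriminant unit-norm filters project the full epoch, and an
evidence-framework Bayesian ridge classifies the flattened projections.
Neither aims at numeric parity with the original implementations; both
share the CV contract.

**Statistics.** Target and non-target ROI FRPs, paired by session, are
compared with two-sided paired t-tests at the 255 causal grid points of
each ROI, followed by one Benjamini-Hochberg pass over the pooled grid.
P3 amplitude is the mean over 300-700 ms (endpoints inclusive). Grand
averages divide each session's ROI measure by the SD of its concatenated
time course so sessions with different numbers of retained components
contribute comparably.

## The simulator and its defaults

One synthetic session emulates the paradigm: a cue moves on a 5x5, +-10
degree grid every 1 s through five auditory-load blocks (silent, ignore,
0/1/2-back), 10% of cues are targets; the eye follows after a ~200 ms
latency with a 30 ms minimum-jerk saccade (0.3 degree landing scatter,
0.05 degree tracker noise at 250 Hz); EEG is mixed at 1,024 Hz from 64
scalp channels plus two mastoids on an 88 mm sphere with a 65 mm brain
sphere centered 15 mm above its center — small enough, and high enough,
that periocular and nuchal generators genuinely fall outside it.

Sources (scalp gains are the largest absolute electrode gain, in
microvolts per unit waveform):

| source | location (mm) | role | default |
| --- | --- | --- | --- |
| lambda | (0,-56,12) occipital | Gaussian bump 100 ms post fixation, SD 20 ms, every fixation | 8 uV, ongoing 0.5 |
| p3 | (0,-35,52) parietal | bump 450 ms, SD 120 ms; x4 on targets; damped by load | 4 uV, ongoing 0.5 |
| vmmn | (8,-52,-14) posterior | negative bump 180 ms, SD 45 ms; x3 on targets; damped by load | -3 uV, ongoing 0.5 |
| 6 background | one per ROI, offset/oblique | amplitude-modulated 1/f noise | 4 uV |
| 2 eyes | (+-30,78,-35) | moment follows gaze angle (corneo-retinal) | 12 uV/deg |
| neck EMG | (0,-80,-45) | sporadic 60-90 Hz bursts | 15 uV |
| sensor noise | — | white, per channel | 2 uV |

Rationale for the key numbers: evoked amplitudes sit in the physiological
few-to-tens-of-microvolts range; target/non-target gains of 4 (P3) and 3
(vMMN) define a strongly separable regime in which recovery failures
indicate pipeline defects rather than statistical bad luck. Each evoked
source also carries ongoing 1/f activity of the same cortical patch
(``ongoing_sd``, in units of the unit-gain bump peak): without it the
recovered component is nearly noise-free and single-trial separability
becomes invariant to condition scaling, so no load effect on Az could
exist in principle. The default load gains decrease gently
(1.0/0.9/0.75/0.6/0.45), with the near-flat silent-to-ignore step the
study design implies; the load-direction experiment instead drives the
generator with an explicitly steeper dial (1.0/0.8/0.6/0.4/0.25) so that
adjacent steps are resolvable at twenty seeds. Amplitude-modulated (hence
super-Gaussian) background noise is what makes the Gaussian-unseparable
rotation problem of plain 1/f sources disappear. Pupil baseline 1000 a.u.
rises 0-12% with load plus slow drift, exercising the relative-pupil
metric in the direction of an arousal effect.

What the simulator does *not* emulate: microsaccades and fixational drift,
blink waveforms, head-movement and electrode-impedance drift, realistic
tissue conductivities (the forward model is a homogeneous medium — only
the linear mixing structure matters to the pipeline), overlapping
responses from short fixations, and between-subject anatomical
variability. Consequently, passing recovery tests shows the chain of
estimators is correct and self-consistent under its own generative
assumptions; it does not certify performance numbers on real recordings.

## Numerical choices and degenerate inputs

* Filters: zero-phase (forward-backward) order-4 Butterworth sections.
* Resampling: polyphase with rational factor and line-padding at edges.
* df rule: bisection on log-lambda in [1e-6, 1e6] x d_max^2; if the
  requested df reaches the rank, lambda = 0 with a warning.
* Ridge: features are centered and scaled on the training data only;
  zero-variance features get scale 1. Wide problems (features > samples)
  are solved in the algebraically identical dual (Gram) form; inside CV
  the Gram eigendecomposition is shared between the penalty search and the
  solve.
* Dipole search: grid bound 1.2x brain radius, candidates at least 2 mm
  from any electrode; refinement tolerance 0.1 mm; scaling a map leaves
  location and residual variance unchanged by construction.
* Zero-variance difference cells in the paired t grid get p = 1 and a
  degeneracy flag; empty ROIs are flagged and refuse to produce measures;
  all-zero scalp maps, non-finite gaze where flagged valid, cutoffs at or
  above Nyquist, and bursts outside the record are rejected with errors.
* Artifact-window statistics are computed once over the whole session.
  Because the window statistic is channel-averaged band power — a
  chi-square variable with roughly 2 x bandwidth x duration x channels
  degrees of freedom — its mean + 3 SD tail is inherently a factor ~2
  heavier than a Gaussian 3-sigma tail; the detector's false-positive
  rate on clean noise is ~0.2-0.5% of windows, not 0.135%.

## Problem sizes used by the validation experiments

The end-to-end recovery experiment runs ten sessions of ~1,000 fixations
(5 x 200 stimuli), the package's standing analog of a multi-participant
study at desk scale; the load-direction experiment averages twenty seeds
of 400-fixation sessions; the acceptance script reproduces the same
quantities at a slightly smaller scale (four recovery sessions, ten load
seeds). These sizes are the package's own choice of a statistically
stable yet routinely re-runnable experiment.

## Known limitations

* The spherical one-layer forward model and toy atlas make dipole
  coordinates internally consistent but not anatomically meaningful.
* ICA is run once per session (argued for in the design: it is
  unsupervised), so CV hygiene covers the supervised stages only.
* Per-condition Az at realistic target counts (~8 per condition per
  session) is noisy; direction tests therefore average over seeds.
* The two eyes share one gaze time course, so their generators form a
  rank-2, co-active artifact subspace whose ICA rotation is arbitrary;
  exclusion is robust to this (any rotation still localizes outside the
  brain), but per-eye attribution is not identifiable.
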