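# frproi

**ROI-resolved fixation-related potentials: single-trial analysis of
co-registered EEG and eye tracking.**

When observers move their eyes freely, stimulus-locked ERP analysis breaks
down: the events of interest are *fixations*, and the EEG around them is
dominated by corneo-retinal (EOG) and muscle artifacts that are
time-locked to the very saccades that define the trials. `frproi`
implements an analysis chain for this setting:

1. **Gaze**: post-hoc quadratic recalibration against cued stimulus
   locations (250 ms oculomotor lag), Engbert-style velocity saccade
   detection (threshold 6 robust SDs, 20 ms / 350 ms minimum durations,
   largest-saccade rule for doublets), 3 degree fixation validity, and a
   relative pupil-size metric.
2. **EEG**: average-mastoid reference, 1 Hz/50 Hz zero-phase filtering,
   resampling to f_s = 256 Hz, and masking of 100 ms windows whose
   90-120 Hz power exceeds mean + 3 SD.
3. **Sources**: ICA over the cleaned session, one equivalent current
   dipole per component under a spherical head model, and exclusion of
   components localizing outside the brain volume — this, not manual
   labeling, is what removes ocular and muscular activity.
4. **Measure projection**: each retained component's fixation-locked
   measure M_i is spread over space as a truncated spherical Gaussian
   (sigma = 12 mm, truncated at 3 sigma) centered at its dipole x_i; the
   expected measure at a location y is

       <M(y)> = sum_i P_i(y) M_i / sum_i P_i(y),

   and six a-priori ROIs (occipital, fusiform, temporal, parietal,
   cingulate, frontal) aggregate it with density-mass weights.
5. **Features and classification**: a 30-scale Morlet basis (minimum
   scale 2/f_s, step 2^0.25) yields per-epoch spectral power; per ROI a
   ridge regression on all features at or below 32 Hz is regularized via
   the effective degrees of freedom

       df(lambda) = sum_j d_j^2 / (d_j^2 + lambda)  =  n_targets,

   and a second-stage LDA fuses the six ROI scores inside one stratified
   5-fold cross-validation (performance: rank-based Az). Ridge weights
   map to Haufe-style forward models for interpretation. HDCA and
   xDAWN+BLDA channel-space comparators share the CV contract.
6. **Statistics**: paired t-tests on the 255 causal grid points x 6 ROIs
   with a single pooled Benjamini-Hochberg correction, and P3 amplitudes
   over 300-700 ms.

Because the paradigm's original recordings are not deposited, the package
ships a first-class synthetic-data module (`frproi.simulate`): 64-channel
EEG at 1,024 Hz mixed from dipolar sources (occipital lambda burst,
target-amplified and load-damped parietal P3 and posterior vMMN, per-ROI
1/f background, gaze-driven eye dipoles, neck EMG), a 1 s-per-stimulus
fixation schedule with 10% targets across five auditory-load conditions,
250 Hz gaze/pupil traces, and the full generative ground truth for
parameter-recovery testing. See `docs/methods.md` for models, defaults
and limitations.

## Worked example

```python
import numpy as np
from frproi.simulate import SimConfig, simulate_session
from frproi.pipeline import PipelineConfig, analyze_session, roi_forward_models

sim = simulate_session(SimConfig(events_per_condition=80), seed=1)
res = analyze_session(sim, PipelineConfig(ica_components=16), seed=1)

print(f"trials: {res.labels.size}  targets: {res.labels.sum()}  "
      f"retained ICs: {res.retained.size}/{res.icset.n_components}")
print("per-ROI Az:",
      {r: round(float(a), 3) for r, a in zip(res.cv.roi_names, res.cv.roi_az)})
print(f"hierarchical Az: {res.cv.hierarchical_az:.3f}")
fwd = roi_forward_models(res, rois=("parietal",))
print(f"parietal discriminant latency: "
      f"{1000 * fwd['parietal'].center_of_mass:.0f} ms")
```

prints (machine-exact values depend on the platform's BLAS):

```
trials: 313  targets: 35  retained ICs: 11/16
per-ROI Az: {'occipital': 0.532, 'fusiform': 0.86, 'temporal': 0.306,
             'parietal': 0.941, 'cingulate': 0.428, 'frontal': 0.468}
hierarchical Az: 0.818
parietal discriminant latency: 495 ms
```

Reading: of 400 cued fixations, 313 survive validity and artifact
screening. The two ROIs where the generator planted class effects carry
the single-trial information — parietal (target-amplified P3, Az 0.94)
and fusiform (the vMMN-like deviance response, Az 0.86) — while ROIs
without planted effects scatter around chance. The parietal forward model
places the discriminant activity at ~500 ms, inside the canonical P3
window. At this small session size the LDA fusion can trail the best
single ROI (six fold-wise score scales on few targets); over full-length
sessions it reliably exceeds it — the end-to-end validation experiment
(ten ~1,000-fixation sessions) yields mean hierarchical Az above 0.9.

A CLI covers the same flow on stored sessions
(`frproi simulate | gaze | classify`); run `frproi --help`.

On-disk formats: EEG as channel-major little-endian float32 with a JSON
sidecar (fs, channel names, electrode positions in mm); gaze and events
as TSV (`t_s, x_deg, y_deg, pupil, valid` / `onset_s, stim_x_deg,
stim_y_deg, is_target, condition`); epoch sets as HDF5 with datasets
`epochs` (trials x series x 332), `times`, `labels`, `conditions` and
attributes `fs`, `series_kind`; the ROI atlas as JSON; dipoles and
projection weights as TSV.

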