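"""End-to-end session analysis: gaze -> preprocessing -> ICA -> dipoles ->
ROI projection -> time-frequency features -> hierarchical classification.

This wires the stage modules together in the order a single recorded
session flows through them; every stage stays individually accessible
for testing and for partial pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify, gaze as gz, preprocess as pp, projection as proj
from . import sources as src
from . import timefreq as tf
from .preprocess import Recording
from .simulate import SimSession


@dataclass
class PipelineConfig:
    """Knobs of the per-session analysis."""

    fs_analysis: float = pp.FS_ANALYSIS
    ica_components: int = 20
    calibration_lag: float = 0.25
    validity_radius_deg: float = 3.0
    sigma_mm: float = proj.SIGMA_MM
    truncation: float = proj.TRUNCATION
    atlas_spacing_mm: float = 8.0
    feature_fmax_hz: float = tf.FEATURE_FMAX
    cv_folds: int = 5
    batch_trials: int = 256      # TF transform chunk size (memory bound)


@dataclass
class SessionResult:
    """Everything one session contributes to the group analysis."""

    cv: classify.CVResult
    roi_names: tuple
    roi_features: list               # per ROI: (trials, n_feat) float32
    roi_frp_epochs: np.ndarray       # (trials, n_rois, n_times)
    times: np.ndarray
    labels: np.ndarray
    conditions: np.ndarray
    weights: proj.ProjectionWeights
    dipoles: list
    retained: np.ndarray
    icset: src.ICSet
    recording: Recording             # preprocessed 256 Hz record
    mask: pp.ArtifactMask
    fixation_onsets: np.ndarray
    n_freq_bins: int
    pupil_by_condition: dict = field(default_factory=dict)
    calibration: gz.CalibrationModel | None = None


def detect_valid_fixations(trace: gz.GazeTrace, events,
                           radius: float = 3.0,
                           lag: float = 0.25,
                           calibrate: bool = True):
    """Recalibrate, detect fixations, and keep the task-valid ones.

    Returns (fixation_onsets, labels, conditions, calibration_model).
    """
    model = None
    if calibrate:
        model = gz.fit_posthoc_calibration(trace, events, lag=lag)
        trace = gz.apply_calibration(trace, model)
    evts = gz.detect_saccades_fixations(trace)
    fixations = [e for e in evts if e.kind == "fixation"]
    valid = gz.validate_fixations(fixations, events, radius=radius)
    onsets = np.array([f.onset for f, v in zip(fixations, valid) if v])
    ev_onsets = np.asarray(events["onset_s"], dtype=float)
    idx = np.searchsorted(ev_onsets, onsets, side="right") - 1
    labels = np.asarray(events["is_target"], dtype=int)[idx]
    conditions = np.asarray(events["condition"], dtype=object)[idx]
    return onsets, labels, conditions, model


def preprocess_recording(rec: Recording) -> tuple[Recording, pp.ArtifactMask]:
    """Mastoid reference, 1 Hz HP, artifact windows at the native rate,
    resample to 256 Hz, 50 Hz LP; mask mapped to the analysis clock."""
    rec = pp.rereference(rec, drop=False)
    rec = pp.highpass(rec, 1.0)
    mask_native = pp.detect_artifact_windows(rec)
    rec = pp.resample(rec, pp.FS_ANALYSIS)
    mask = mask_native.resample_to(rec.fs, rec.n_samples)
    rec = pp.lowpass(rec, 50.0)
    return rec, mask


def analyze_session(sim: SimSession, config: PipelineConfig | None = None,
                    seed: int = 0) -> SessionResult:
    """Run the full single-session analysis on a simulated session."""
    config = config or PipelineConfig()
    head = sim.head

    onsets, labels, conditions, cal = detect_valid_fixations(
        sim.gaze, sim.events, radius=config.validity_radius_deg,
        lag=config.calibration_lag)

    rec_raw = Recording(data=sim.eeg, fs=sim.fs_eeg,
                        channel_names=sim.channel_names,
                        electrode_positions=head.electrode_positions)
    rec, mask = preprocess_recording(rec_raw)

    # ICA on the artifact-excised record; activations on the full record
    clean = pp.clean_record(rec, mask)
    icset = src.run_ica(clean, n_components=config.ica_components, seed=seed)
    acts = icset.unmixing @ (rec.data - icset.mean[:, None])

    mast = [i for i, n in enumerate(rec.channel_names) if n.startswith("M")]
    dipoles = [src.fit_equivalent_dipole(icset.scalp_map(i), head,
                                         reference_rows=mast or None)
               for i in range(icset.n_components)]
    retained = src.select_brain_ics(dipoles, head.brain_volume)
    if retained.size == 0:
        raise RuntimeError("no components localized inside the brain")

    epochs = pp.extract_epochs(acts[retained], rec.fs, onsets, labels,
                               conditions, mask=mask, series_kind="ic")

    atlas = proj.toy_atlas(head, spacing=config.atlas_spacing_mm)
    vox, _ = atlas.stacked()
    density = proj.dipole_density(
        np.stack([dipoles[i].location for i in retained]), vox,
        sigma=config.sigma_mm, truncation=config.truncation)
    weights = proj.roi_weights(density, atlas)
    roi_names = tuple(n for n in atlas.names if n not in weights.empty_rois)

    # time-domain ROI FRP epochs
    roi_frp = np.stack([proj.roi_measure(epochs.epochs.transpose(1, 0, 2),
                                         weights, r) for r in roi_names],
                       axis=1)                       # (trials, rois, times)

    # time-frequency ROI features: mix per-IC power with the ROI weights
    basis = tf.build_basis(fs=rec.fs)
    bins = basis.feature_bins(config.feature_fmax_hz)
    sub = tf.WaveletBasis(fs=basis.fs, omega0=basis.omega0,
                          scales=basis.scales[bins], freqs=basis.freqs[bins],
                          dj=basis.dj)
    n_trials, _, n_times = epochs.epochs.shape
    n_feat = bins.size * n_times
    roi_idx = {r: weights.roi_names.index(r) for r in roi_names}
    feats = [np.zeros((n_trials, n_feat), dtype=np.float32)
             for _ in roi_names]
    for pos, ic in enumerate(retained):
        w_ic = weights.w[pos]
        if not np.any(w_ic > 0):
            continue
        for lo in range(0, n_trials, config.batch_trials):
            sl = slice(lo, min(lo + config.batch_trials, n_trials))
            p = tf.batch_power(epochs.epochs[sl, pos, :], sub, fmax=None)
            flat = p.reshape(p.shape[0], -1).astype(np.float32)
            for j, r in enumerate(roi_names):
                wj = w_ic[roi_idx[r]]
                if wj > 0:
                    feats[j][sl] += np.float32(wj) * flat

    cv = classify.cross_validate(feats, epochs.labels, roi_names=roi_names,
                                 k=config.cv_folds, seed=seed)

    pupil = {}
    try:
        pupil = gz.relative_pupil(sim.gaze, sim.condition_intervals())
    except (ValueError, AttributeError):
        pass

    return SessionResult(cv=cv, roi_names=roi_names, roi_features=feats,
                         roi_frp_epochs=roi_frp, times=epochs.times,
                         labels=epochs.labels, conditions=epochs.conditions,
                         weights=weights, dipoles=dipoles, retained=retained,
                         icset=icset, recording=rec, mask=mask,
                         fixation_onsets=onsets, n_freq_bins=bins.size,
                         pupil_by_condition=pupil, calibration=cal)


def roi_forward_models(result: SessionResult, rois=None) -> dict:
    """Full-data ridge per ROI plus its Haufe-style forward model."""
    out = {}
    n_times = result.times.size
    shape = (result.n_freq_bins, n_times)
    n_target = int(np.sum(result.labels == 1))
    for j, roi in enumerate(result.roi_names):
        if rois is not None and roi not in rois:
            continue
        X = result.roi_features[j].astype(float)
        Z, center, scale = classify._standardize(X)
        lam = classify.select_lambda(Z, n_target)
        model = classify.fit_ridge(X, result.labels.astype(float), lam)
        scores = model.predict(X)
        out[roi] = classify.forward_model(Z, model.coef, scores,
                                          feature_shape=shape,
                                          times=result.times)
    return out


def mean_frps(result: SessionResult, normalize: bool = True):
    """(target, non-target) mean ROI FRPs, optionally variance-scaled."""
    t = result.roi_frp_epochs[result.labels == 1].mean(axis=0)
    n = result.roi_frp_epochs[result.labels == 0].mean(axis=0)
    if normalize:
        sd = np.std(np.concatenate([t.ravel(), n.ravel()]))
        if sd > 0:
            t, n = t / sd, n / sd
    return t, n
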