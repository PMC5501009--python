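"""Gaze processing: post-hoc recalibration, saccade/fixation detection,
fixation validity, and the relative pupil metric.

The recalibration exploits the task structure: during guided viewing the
eye is expected to land on the cued stimulus, so the cue locations (after a
fixed oculomotor lag) serve as regression targets for a per-axis quadratic
correction of the raw gaze signal.

Saccades are detected with a velocity-threshold algorithm in the style of
Engbert & Mergenthaler: sample-to-sample velocity from a 5-sample central
moving difference, per-axis thresholds at ``velocity_factor`` robust
standard deviations of the velocity distribution (median-based estimator),
and an elliptic combination of the two axes.  Detected saccades shorter
than 20 ms are discarded; fixations are the inter-saccade intervals of at
least 350 ms.  When two saccades fall within a 350 ms window only the
fixation corresponding to the larger saccade is preserved (the smaller,
corrective saccade is absorbed into the fixation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# containers


@dataclass
class GazeTrace:
    """Monocular (or eye-averaged) gaze/pupil trace in degrees of visual angle."""

    t: np.ndarray          # s, strictly increasing
    x: np.ndarray          # deg
    y: np.ndarray          # deg
    pupil: np.ndarray      # arbitrary units
    valid: np.ndarray      # bool per sample
    fs: float              # Hz

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("gaze time axis must be strictly increasing")
        bad = ~(np.isfinite(self.x) & np.isfinite(self.y))
        if np.any(bad & self.valid):
            # non-finite samples are never valid
            self.valid = self.valid & ~bad

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class CalibrationModel:
    """Per-axis quadratic gaze correction: corrected = a0 + a1*raw + a2*raw^2."""

    coef_x: np.ndarray     # (a0, a1, a2)
    coef_y: np.ndarray
    lag: float             # s, oculomotor lag applied to the expected position
    rmse_x: float = np.nan
    rmse_y: float = np.nan

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        for c in (self.coef_x, self.coef_y):
            if not np.all(np.isfinite(c)):
                raise ValueError("calibration coefficients must be finite")


@dataclass(frozen=True)
class EyeEvent:
    """A saccade or fixation."""

    kind: str                      # "saccade" | "fixation"
    onset: float                   # s
    offset: float                  # s
    amplitude: float = np.nan      # deg (saccades: displacement)
    peak_velocity: float = np.nan  # deg/s
    landing_position: tuple = (np.nan, np.nan)  # deg (fixations)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


# ---------------------------------------------------------------------------
# post-hoc calibration


def _quad_design(v: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(v), v, v**2])


def fit_posthoc_calibration(
    gaze: GazeTrace,
    events: pd.DataFrame,
    lag: float = 0.25,
    interval: float = 1.0,
) -> CalibrationModel:
    """Fit the quadratic raw->expected correction from cue positions.

    Each stimulus interval ``[onset, onset + interval)`` contributes the
    raw gaze samples in ``[onset + lag, onset + interval)``, paired with
    the stimulus position active at ``onset``; the lag absorbs the delay
    between cue onset and the landing of the responding saccade.

    Parameters
    ----------
    events : DataFrame
        Columns ``onset_s``, ``stim_x_deg``, ``stim_y_deg``.

    Raises
    ------
    ValueError
        If fewer than 10 paired samples survive, or the design is
        rank-deficient (e.g. constant raw gaze).
    """
    raws, exps = [], []
    onsets = np.asarray(events["onset_s"], dtype=float)
    for onset, sx, sy in zip(onsets, events["stim_x_deg"], events["stim_y_deg"]):
        sel = (gaze.t >= onset + lag) & (gaze.t < onset + interval) & gaze.valid
        if not np.any(sel):
            continue
        raws.append(np.column_stack([gaze.x[sel], gaze.y[sel]]))
        exps.append(np.tile([sx, sy], (int(sel.sum()), 1)))
    if not raws:
        raise ValueError("no paired samples for calibration")
    raw = np.vstack(raws)
    exp = np.vstack(exps)
    if raw.shape[0] < 10:
        raise ValueError("need >= 10 paired samples per axis for calibration")

    coefs, rmses = [], []
    for ax in range(2):
        design = _quad_design(raw[:, ax])
        if np.linalg.matrix_rank(design) < 3:
            raise ValueError("rank-deficient calibration design (constant gaze?)")
        coef, *_ = np.linalg.lstsq(design, exp[:, ax], rcond=None)
        resid = design @ coef - exp[:, ax]
        coefs.append(coef)
        rmses.append(float(np.sqrt(np.mean(resid**2))))
    return CalibrationModel(
        coef_x=coefs[0], coef_y=coefs[1], lag=lag, rmse_x=rmses[0], rmse_y=rmses[1]
    )


def apply_calibration(gaze: GazeTrace, model: CalibrationModel) -> GazeTrace:
    """Evaluate the per-axis quadratic; time, pupil, validity untouched.

    Non-finite samples pass through unchanged (they are already flagged
    invalid by the trace constructor).
    """
    x = np.where(
        np.isfinite(gaze.x), _quad_design(np.nan_to_num(gaze.x)) @ model.coef_x, gaze.x
    )
    y = np.where(
        np.isfinite(gaze.y), _quad_design(np.nan_to_num(gaze.y)) @ model.coef_y, gaze.y
    )
    return replace(gaze, x=x, y=y)


# ---------------------------------------------------------------------------
# saccade / fixation detection


def _engbert_velocity(pos: np.ndarray, dt: float) -> np.ndarray:
    """5-sample central moving difference, deg/s; edges use shorter stencils."""
    v = np.zeros_like(pos)
    v[2:-2] = (pos[4:] + pos[3:-1] - pos[1:-3] - pos[:-4]) / (6.0 * dt)
    v[1] = (pos[2] - pos[0]) / (2.0 * dt)
    v[-2] = (pos[-1] - pos[-3]) / (2.0 * dt)
    return v


def _robust_sigma(v: np.ndarray) -> float:
    """Median-based velocity spread: sqrt(<v^2>_med - <v>_med^2)."""
    var = np.median(v**2) - np.median(v) ** 2
    if var <= 0:
        var = np.var(v)
    return float(np.sqrt(var))


def detect_saccades_fixations(
    gaze: GazeTrace,
    velocity_factor: float = 6.0,
    min_saccade: float = 0.020,
    min_fixation: float = 0.350,
    doublet_window: float = 0.350,
) -> list[EyeEvent]:
    """Velocity-threshold saccade detection plus inter-saccade fixations.

    Returns a time-ordered list of EyeEvents.  Traces shorter than
    ``2 * min_fixation`` yield an empty list.
    """
    n = len(gaze)
    dt = 1.0 / gaze.fs
    if n * dt < 2 * min_fixation:
        return []
    vx = _engbert_velocity(gaze.x, dt)
    vy = _engbert_velocity(gaze.y, dt)
    eta_x = velocity_factor * _robust_sigma(vx)
    eta_y = velocity_factor * _robust_sigma(vy)
    if eta_x <= 0 or eta_y <= 0:
        return [_fixation_from_span(gaze, 0, n - 1)]
    crit = (vx / eta_x) ** 2 + (vy / eta_y) ** 2 > 1.0
    speed = np.hypot(vx, vy)

    # runs of supra-threshold samples
    padded = np.diff(np.concatenate([[0], crit.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1  # inclusive
    saccades = []
    for i0, i1 in zip(starts, ends):
        if (i1 - i0 + 1) * dt < min_saccade:
            continue
        amp = float(np.hypot(gaze.x[i1] - gaze.x[i0], gaze.y[i1] - gaze.y[i0]))
        saccades.append(
            EyeEvent(
                kind="saccade",
                onset=float(gaze.t[i0]),
                offset=float(gaze.t[i1]),
                amplitude=amp,
                peak_velocity=float(speed[i0 : i1 + 1].max()),
            )
        )

    # largest-saccade rule: of two saccades within the doublet window, the
    # smaller is absorbed so only the fixation after the larger survives
    saccades = _resolve_doublets(saccades, doublet_window)

    events: list[EyeEvent] = list(saccades)
    bounds = [gaze.t[0]] + [s.offset for s in saccades]
    uppers = [s.onset for s in saccades] + [gaze.t[-1]]
    for lo, hi in zip(bounds, uppers):
        if hi - lo < min_fixation:
            continue
        sel = (gaze.t >= lo) & (gaze.t <= hi)
        i0, i1 = np.flatnonzero(sel)[[0, -1]]
        events.append(_fixation_from_span(gaze, i0, i1))
    events.sort(key=lambda e: e.onset)
    return events


def _fixation_from_span(gaze: GazeTrace, i0: int, i1: int) -> EyeEvent:
    return EyeEvent(
        kind="fixation",
        onset=float(gaze.t[i0]),
        offset=float(gaze.t[i1]),
        landing_position=(
            float(np.median(gaze.x[i0 : i1 + 1])),
            float(np.median(gaze.y[i0 : i1 + 1])),
        ),
    )


def _resolve_doublets(saccades: list[EyeEvent], window: float) -> list[EyeEvent]:
    saccades = sorted(saccades, key=lambda s: s.onset)
    changed = True
    while changed and len(saccades) > 1:
        changed = False
        for i in range(len(saccades) - 1):
            if saccades[i + 1].onset - saccades[i].onset <= window:
                drop = i if saccades[i].amplitude < saccades[i + 1].amplitude else i + 1
                del saccades[drop]
                changed = True
                break
    return saccades


# ---------------------------------------------------------------------------
# fixation validity and pupil


def validate_fixations(
    fixations: Sequence[EyeEvent],
    events: pd.DataFrame,
    radius: float = 3.0,
) -> np.ndarray:
    """Flag fixations landing within ``radius`` degrees of the active stimulus.

    The active stimulus is the most recent event with onset <= fixation
    onset; fixations before the first stimulus are invalid.
    """
    onsets = np.asarray(events["onset_s"], dtype=float)
    sx = np.asarray(events["stim_x_deg"], dtype=float)
    sy = np.asarray(events["stim_y_deg"], dtype=float)
    order = np.argsort(onsets)
    onsets, sx, sy = onsets[order], sx[order], sy[order]
    out = np.zeros(len(fixations), dtype=bool)
    for i, fx in enumerate(fixations):
        j = np.searchsorted(onsets, fx.onset, side="right") - 1
        if j < 0:
            continue
        d = np.hypot(fx.landing_position[0] - sx[j], fx.landing_position[1] - sy[j])
        out[i] = d <= radius
    return out


def relative_pupil(
    gaze: GazeTrace, condition_intervals: dict[str, list[tuple[float, float]]]
) -> dict[str, float]:
    """Mean pupil size per condition relative to the whole-session mean.

    Invalid samples are excluded from both numerator and denominator.
    """
    ok = gaze.valid & np.isfinite(gaze.pupil)
    session_mean = float(np.mean(gaze.pupil[ok]))
    if session_mean == 0:
        raise ValueError("session mean pupil size is zero")
    out = {}
    for cond, spans in condition_intervals.items():
        sel = np.zeros(len(gaze), dtype=bool)
        for lo, hi in spans:
            sel |= (gaze.t >= lo) & (gaze.t < hi)
        sel &= ok
        if not np.any(sel):
            raise ValueError(f"condition {cond!r} has no valid pupil samples")
        out[cond] = float(np.mean(gaze.pupil[sel])) / session_mean
    return out
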