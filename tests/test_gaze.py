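"""Gaze calibration, saccade/fixation detection, validity, pupil metric."""

import numpy as np
import pandas as pd
import pytest

from frproi.gaze import (CalibrationModel, GazeTrace, apply_calibration,
                         detect_saccades_fixations, fit_posthoc_calibration,
                         relative_pupil, validate_fixations)
from frproi.simulate import minimum_jerk

FS = 250.0


def _trace(x, y, fs=FS, pupil=None, valid=None):
    n = len(x)
    return GazeTrace(t=np.arange(n) / fs, x=np.asarray(x, float),
                     y=np.asarray(y, float),
                     pupil=np.ones(n) if pupil is None else pupil,
                     valid=np.ones(n, bool) if valid is None else valid,
                     fs=fs)


def _step_schedule(positions, fs=FS, dwell=1.0):
    """Gaze that jumps instantly to each stimulus and stays there."""
    x = np.repeat([p[0] for p in positions], int(dwell * fs))
    y = np.repeat([p[1] for p in positions], int(dwell * fs))
    events = pd.DataFrame({
        "onset_s": np.arange(len(positions)) * dwell,
        "stim_x_deg": [p[0] for p in positions],
        "stim_y_deg": [p[1] for p in positions],
    })
    return x, y, events


# ---------------------------------------------------------------------------
# calibration


class TestCalibration:
    POSITIONS = [(-8, -5), (0, 3), (8, -2), (-4, 6), (5, 5), (2, -7),
                 (-6, 1), (7, 2), (0, -4), (-2, 8)]

    def test_identity_when_raw_equals_expected(self):
        x, y, events = _step_schedule(self.POSITIONS)
        model = fit_posthoc_calibration(_trace(x, y), events)
        assert np.allclose(model.coef_x, [0, 1, 0], atol=1e-8)
        assert np.allclose(model.coef_y, [0, 1, 0], atol=1e-8)

    def test_quadratic_distortion_inverted(self):
        x, y, events = _step_schedule(self.POSITIONS)
        raw_x = 0.5 + 0.9 * x + 0.01 * x**2
        raw_y = -0.3 + 1.1 * y - 0.02 * y**2
        trace = _trace(raw_x, raw_y)
        model = fit_posthoc_calibration(trace, events)
        corrected = apply_calibration(trace, model)
        rmse = np.sqrt(np.mean((corrected.x - x) ** 2 + (corrected.y - y) ** 2))
        assert rmse < 0.1
        # idempotence: a second fit+apply changes positions negligibly
        model2 = fit_posthoc_calibration(corrected, events)
        twice = apply_calibration(corrected, model2)
        assert np.sqrt(np.mean((twice.x - corrected.x) ** 2)) < 0.05

    def test_lag_matches_oculomotor_delay(self):
        """With a 250 ms landing delay, the lagged fit has lower residual."""
        x, y, events = _step_schedule(self.POSITIONS)
        shift = int(0.25 * FS)
        x_lag = np.concatenate([x[:1].repeat(shift), x[:-shift]])
        y_lag = np.concatenate([y[:1].repeat(shift), y[:-shift]])
        lagged = fit_posthoc_calibration(_trace(x_lag, y_lag), events, lag=0.25)
        unlagged = fit_posthoc_calibration(_trace(x_lag, y_lag), events, lag=0.0)
        assert lagged.rmse_x < unlagged.rmse_x
        assert lagged.rmse_y < unlagged.rmse_y

    def test_constant_gaze_rejected(self):
        x, y, events = _step_schedule(self.POSITIONS)
        with pytest.raises(ValueError):
            fit_posthoc_calibration(_trace(np.zeros_like(x), y), events)

    def test_apply_identity_and_nan_passthrough(self):
        ident = CalibrationModel(coef_x=np.array([0.0, 1.0, 0.0]),
                                 coef_y=np.array([0.0, 1.0, 0.0]), lag=0.25)
        x = np.linspace(-5, 5, 300)
        x[10] = np.nan
        trace = _trace(x, np.zeros_like(x))
        out = apply_calibration(trace, ident)
        assert np.isnan(out.x[10]) and not out.valid[10]
        good = np.isfinite(x)
        assert np.allclose(out.x[good], x[good])
        assert out.pupil is trace.pupil or np.allclose(out.pupil, trace.pupil)


# ---------------------------------------------------------------------------
# saccade / fixation detection


def _saccade_trace(steps, fs=FS, dwell=1.0, noise=0.0, sacc_dur=0.030,
                   seed=0):
    """Piecewise-constant gaze with minimum-jerk steps at dwell boundaries."""
    rng = np.random.default_rng(seed)
    n = int(dwell * fs * (len(steps) + 1))
    t = np.arange(n) / fs
    x = np.zeros(n)
    cur = 0.0
    for k, amp in enumerate(steps):
        t0 = (k + 1) * dwell
        tau = np.clip((t - t0) / sacc_dur, 0, 1)
        x = np.where(t >= t0, cur + amp * minimum_jerk(tau), x)
        cur += amp
    x = x + noise * rng.standard_normal(n)
    y = noise * rng.standard_normal(n)
    return _trace(x, y, fs=fs)


class TestDetection:
    def test_pure_noise_one_fixation_no_saccades(self):
        rng = np.random.default_rng(3)
        trace = _trace(0.05 * rng.standard_normal(2500),
                       0.05 * rng.standard_normal(2500))
        events = detect_saccades_fixations(trace)
        kinds = [e.kind for e in events]
        assert kinds.count("saccade") == 0
        assert kinds.count("fixation") == 1
        fix = events[0]
        assert fix.onset == trace.t[0] and fix.offset == trace.t[-1]

    def test_single_step_one_saccade_two_fixations(self):
        trace = _saccade_trace([5.0], noise=0.02)
        events = detect_saccades_fixations(trace)
        saccades = [e for e in events if e.kind == "saccade"]
        fixations = [e for e in events if e.kind == "fixation"]
        assert len(saccades) == 1
        assert len(fixations) == 2
        assert saccades[0].amplitude == pytest.approx(5.0, abs=0.5)
        assert 0.95 <= saccades[0].onset <= 1.05

    def test_largest_saccade_rule_on_doublet(self):
        """Two saccades 100 ms apart: only the fixation tied to the larger
        (5 deg) one survives; the 1 deg corrective saccade is absorbed."""
        fs = FS
        dwell = 1.0
        n = int(3.2 * fs)
        t = np.arange(n) / fs
        x = np.zeros(n)
        for t0, amp, start in [(1.0, 5.0, 0.0), (1.1, 1.0, 5.0)]:
            tau = np.clip((t - t0) / 0.020, 0, 1)
            x = np.where(t >= t0, start + amp * minimum_jerk(tau), x)
        rng = np.random.default_rng(1)
        trace = _trace(x + 0.02 * rng.standard_normal(n),
                       0.02 * rng.standard_normal(n))
        events = detect_saccades_fixations(trace)
        saccades = [e for e in events if e.kind == "saccade"]
        fixations = [e for e in events if e.kind == "fixation"]
        assert len(saccades) == 1
        assert saccades[0].amplitude == pytest.approx(5.0, abs=0.6)
        # fixation following the big saccade survives (plus the initial one)
        assert len(fixations) == 2
        assert fixations[1].onset >= saccades[0].offset

    def test_threshold_scale_invariance(self):
        trace = _saccade_trace([5.0, -3.0, 4.0], noise=0.03, seed=5)
        scaled = GazeTrace(t=trace.t, x=7.0 * trace.x, y=7.0 * trace.y,
                           pupil=trace.pupil, valid=trace.valid, fs=trace.fs)
        ev1 = detect_saccades_fixations(trace)
        ev2 = detect_saccades_fixations(scaled)
        assert [(e.kind, e.onset) for e in ev1] == [(e.kind, e.onset)
                                                   for e in ev2]

    def test_short_trace_empty(self):
        trace = _trace(np.zeros(50), np.zeros(50))
        assert detect_saccades_fixations(trace) == []


# ---------------------------------------------------------------------------
# validity and pupil


def test_validate_fixations_radius_boundary():
    from frproi.gaze import EyeEvent
    events = pd.DataFrame({"onset_s": [1.0], "stim_x_deg": [0.0],
                           "stim_y_deg": [0.0]})
    mk = lambda x, onset=2.0: EyeEvent(kind="fixation", onset=onset,
                                       offset=onset + 0.5,
                                       landing_position=(x, 0.0))
    flags = validate_fixations([mk(0.0), mk(2.99), mk(3.01), mk(0.0, 0.5)],
                               events, radius=3.0)
    assert flags.tolist() == [True, True, False, False]


class TestRelativePupil:
    def test_condition_ratios_arithmetic(self):
        n = 1000
        pupil = np.where(np.arange(n) < n // 2, 4.0, 5.0)
        trace = _trace(np.zeros(n), np.zeros(n), pupil=pupil)
        spans = {"a": [(0.0, (n // 2) / FS)], "b": [((n // 2) / FS, n / FS)]}
        ratios = relative_pupil(trace, spans)
        assert ratios["a"] == pytest.approx(4.0 / 4.5)
        assert ratios["b"] == pytest.approx(5.0 / 4.5)
        # scale invariance
        trace2 = _trace(np.zeros(n), np.zeros(n), pupil=3.7 * pupil)
        ratios2 = relative_pupil(trace2, spans)
        assert ratios2["a"] == pytest.approx(ratios["a"])

    def test_constant_pupil_all_ones(self):
        trace = _trace(np.zeros(500), np.zeros(500))
        ratios = relative_pupil(trace, {"c": [(0.0, 1.0)]})
        assert ratios["c"] == pytest.approx(1.0)

    def test_zero_session_mean_rejected(self):
        trace = _trace(np.zeros(500), np.zeros(500), pupil=np.zeros(500))
        with pytest.raises(ValueError):
            relative_pupil(trace, {"c": [(0.0, 1.0)]})
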