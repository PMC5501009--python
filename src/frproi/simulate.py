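"""Ground-truthed synthetic sessions: EEG, gaze, pupil and event schedule.

The generator emulates a guided visual-search paradigm with a concurrent
auditory n-back load manipulation: a cue moves to a new grid location
every second, the eye follows with a ~200 ms latency and a 30 ms
minimum-jerk saccade, and 10% of cued stimuli are targets.  EEG is
synthesized at 1,024 Hz from 64 scalp channels (plus mastoids) by mixing
point-dipole sources through the spherical forward model:

* a ``lambda_burst`` source in occipital cortex — a sharp positivity
  ~100 ms after every fixation onset (the saccade-locked analog of P1);
* a ``p3_wave`` source in parietal cortex — a slow positivity peaking
  ~450 ms, amplified on target fixations (``class_gain``) and scaled
  down monotonically with auditory working-memory load
  (``condition_gains``);
* per-region ``background_pink`` sources — amplitude-modulated 1/f noise
  (the modulation makes them super-Gaussian, hence separable by ICA);
* two ``eog_gaze_linked`` sources at the eyes, outside the brain volume,
  whose dipole moment follows the instantaneous gaze angle — the
  corneo-retinal artifact the source-exclusion step must catch;
* an optional ``emg_burst`` neck-muscle source emitting sporadic
  high-frequency bursts.

Everything is reproducible from (config, seed), and the full generative
truth (source patterns, activations, fixation onsets, artifact windows)
is stored on the session for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, sosfiltfilt

from .gaze import GazeTrace
from .headmodel import HeadModel, leadfield_basis, standard_head

CONDITIONS = ("silent", "ignore", "0-back", "1-back", "2-back")

NEURAL_KINDS = {"lambda_burst", "p3_wave", "background_pink"}
ARTIFACT_KINDS = {"eog_gaze_linked", "emg_burst"}


@dataclass
class SourceSpec:
    """One generative source: location, scalp gain, waveform family.

    ``amplitude`` is calibrated at the scalp: the channel pattern is the
    unit-moment leadfield rescaled so its largest absolute electrode gain
    equals ``amplitude`` (microvolts per unit of the source waveform).
    Neural kinds must lie inside the brain volume, artifact kinds outside.
    """

    name: str
    kind: str
    location: tuple
    amplitude: float
    class_gain: float = 1.0
    condition_gains: dict = field(default_factory=dict)
    latency: float = 0.0       # s post fixation (bump kinds)
    width: float = 0.05        # s, Gaussian bump SD
    ongoing_sd: float = 0.0    # ongoing 1/f activity of the same patch,
                               # in units of the unit-gain bump peak
    band: tuple = (60.0, 90.0)  # Hz (emg bursts)
    orientation: tuple | None = None  # dipole moment direction; default radial

    def moment_direction(self) -> np.ndarray:
        if self.orientation is not None:
            m = np.asarray(self.orientation, dtype=float)
        else:
            loc = np.asarray(self.location, dtype=float)
            m = loc if np.linalg.norm(loc) > 1e-6 else np.array([0.0, 0.0, 1.0])
        return m / np.linalg.norm(m)


def default_sources() -> list[SourceSpec]:
    """Sources emulating the paradigm's known electrophysiology."""
    load_gains = {
        "silent": 1.0, "ignore": 0.9, "0-back": 0.75, "1-back": 0.6, "2-back": 0.45,
    }
    srcs = [
        SourceSpec("lambda", "lambda_burst", (0.0, -56.0, 12.0),
                   amplitude=8.0, latency=0.100, width=0.020,
                   ongoing_sd=0.5),
        SourceSpec("p3", "p3_wave", (0.0, -35.0, 52.0),
                   amplitude=4.0, class_gain=4.0, condition_gains=load_gains,
                   latency=0.450, width=0.120, ongoing_sd=0.5),
        # early posterior deviance response (vMMN-like): a negative
        # deflection stronger on targets, also damped by auditory load
        SourceSpec("vmmn", "p3_wave", (8.0, -52.0, -14.0),
                   amplitude=-3.0, class_gain=3.0, condition_gains=load_gains,
                   latency=0.180, width=0.045, ongoing_sd=0.5),
    ]
    # one resting generator per region, offset from the evoked sources and
    # obliquely oriented so scalp maps stay distinguishable
    bg_locs = {
        "bg_occipital": ((18.0, -52.0, 16.0), (0.3, 1.0, 0.0)),
        "bg_fusiform": ((-10.0, -44.0, -16.0), None),
        "bg_temporal": ((52.0, -18.0, -8.0), None),
        "bg_parietal": ((-16.0, -36.0, 38.0), (1.0, 0.0, 0.3)),
        "bg_cingulate": ((4.0, 4.0, 32.0), None),
        "bg_frontal": ((-6.0, 45.0, 28.0), None),
    }
    for name, (loc, ori) in bg_locs.items():
        srcs.append(SourceSpec(name, "background_pink", loc, amplitude=4.0,
                               orientation=ori))
    srcs += [
        SourceSpec("eog_left", "eog_gaze_linked", (-30.0, 78.0, -35.0), amplitude=12.0),
        SourceSpec("eog_right", "eog_gaze_linked", (30.0, 78.0, -35.0), amplitude=12.0),
        SourceSpec("emg_neck", "emg_burst", (0.0, -80.0, -45.0),
                   amplitude=15.0, band=(60.0, 90.0)),
    ]
    return srcs


@dataclass
class SimConfig:
    """Study conditions for one synthetic session."""

    fs_eeg: float = 1024.0
    fs_gaze: float = 250.0
    events_per_condition: int = 200          # x5 conditions, 1 s per stimulus
    conditions: tuple = CONDITIONS
    target_fraction: float = 0.10
    grid_extent_deg: float = 10.0            # 5x5 grid spanning +-extent
    grid_points: int = 5
    saccade_latency: float = 0.200           # s, mean cue->saccade-onset
    saccade_latency_sd: float = 0.020
    saccade_duration: float = 0.030          # s, minimum-jerk profile
    landing_noise_deg: float = 0.3
    gaze_noise_deg: float = 0.05             # white measurement noise
    pupil_base: float = 1000.0
    pupil_load_gains: dict = field(default_factory=lambda: {
        "silent": 0.0, "ignore": 0.02, "0-back": 0.05,
        "1-back": 0.08, "2-back": 0.12,
    })
    pupil_noise: float = 8.0                 # slow drift SD, a.u.
    sensor_noise_uv: float = 2.0
    amplitude_jitter: float = 0.2            # lognormal sigma on evoked bumps
    emg_rate_hz: float = 0.01
    sources: list = field(default_factory=default_sources)
    head: HeadModel = field(default_factory=standard_head)

    def validate(self) -> None:
        for key, val in asdict(self).items():
            if key in ("sources", "head", "conditions"):
                continue
            arr = np.asarray(
                list(val.values()) if isinstance(val, dict) else val, dtype=float
            )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite config value in {key!r}")
        brain = self.head.brain_volume
        for src in self.sources:
            inside = bool(brain.contains(np.asarray(src.location))[0])
            if src.kind in NEURAL_KINDS and not inside:
                raise ValueError(f"neural source {src.name!r} outside brain volume")
            if src.kind in ARTIFACT_KINDS and inside:
                raise ValueError(f"artifact source {src.name!r} inside brain volume")


@dataclass
class SimSession:
    """One simulated recording with its generative ground truth."""

    eeg: np.ndarray              # (n_channels, n_samples) microvolts
    fs_eeg: float
    head: HeadModel
    gaze: GazeTrace
    events: pd.DataFrame         # onset_s, stim_x_deg, stim_y_deg, is_target,
                                 # condition, fixation_onset_s
    truth: dict                  # sources, patterns, activations, ...

    @property
    def channel_names(self) -> tuple:
        return self.head.channel_names

    def condition_intervals(self) -> dict[str, list[tuple[float, float]]]:
        out: dict[str, list[tuple[float, float]]] = {}
        ev = self.events
        for cond in ev["condition"].unique():
            t = ev.loc[ev["condition"] == cond, "onset_s"].to_numpy()
            out[str(cond)] = [(float(t.min()), float(t.max()) + 1.0)]
        return out


# ---------------------------------------------------------------------------
# building blocks


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def pink_noise(n: int, fs: float, rng: np.random.Generator,
               knee_hz: float = 1.0, modulated: bool = True) -> np.ndarray:
    """Unit-variance 1/f noise, optionally amplitude-modulated.

    The slow (tau ~ 0.5 s) positive envelope mimics waxing-and-waning
    oscillatory background and gives the source the super-Gaussian
    statistics ICA needs.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec *= 1.0 / np.sqrt(np.maximum(f, knee_hz))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    if modulated:
        env = gaussian_filter1d(rng.standard_normal(n), sigma=0.5 * fs)
        env = 1.0 + env / (np.std(env) + 1e-12)
        x *= np.clip(env, 0.1, None)
    return x / np.std(x)


def _bump_train(n: int, fs: float, centers: np.ndarray, amps: np.ndarray,
                width: float) -> np.ndarray:
    """Sum of unit-peak Gaussian bumps at the given times, scaled by amps."""
    out = np.zeros(n)
    half = int(round(4 * width * fs))
    for c, a in zip(centers, amps):
        i = int(round(c * fs))
        lo, hi = max(i - half, 0), min(i + half + 1, n)
        if lo >= hi:
            continue
        t = (np.arange(lo, hi) / fs) - c
        out[lo:hi] += a * np.exp(-0.5 * (t / width) ** 2)
    return out


def _scalp_pattern(src: SourceSpec, head: HeadModel,
                   direction: np.ndarray | None = None) -> np.ndarray:
    B = leadfield_basis(np.asarray(src.location, dtype=float), head)
    d = src.moment_direction() if direction is None else np.asarray(direction, float)
    pat = B @ d
    peak = np.max(np.abs(pat))
    return src.amplitude * pat / peak


def _gaze_path(t: np.ndarray, schedule: pd.DataFrame, start_xy: np.ndarray,
               sacc_duration: float) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless gaze trajectory through the per-event saccade plan."""
    n = t.size
    x = np.empty(n)
    y = np.empty(n)
    cur = np.asarray(start_xy, dtype=float).copy()
    prev = 0
    onsets = schedule["saccade_onset_s"].to_numpy()
    lx = schedule["land_x_deg"].to_numpy()
    ly = schedule["land_y_deg"].to_numpy()
    i0s = np.searchsorted(t, onsets)
    for k in range(len(onsets)):
        i0 = int(i0s[k])
        i1 = min(int(np.searchsorted(t, onsets[k] + sacc_duration)) + 1, n)
        x[prev:i0] = cur[0]
        y[prev:i0] = cur[1]
        prof = minimum_jerk((t[i0:i1] - onsets[k]) / sacc_duration)
        x[i0:i1] = cur[0] + (lx[k] - cur[0]) * prof
        y[i0:i1] = cur[1] + (ly[k] - cur[1]) * prof
        cur = np.array([lx[k], ly[k]])
        prev = i1
    x[prev:] = cur[0]
    y[prev:] = cur[1]
    return x, y


# ---------------------------------------------------------------------------
# session assembly


def _event_schedule(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    grid = np.linspace(-config.grid_extent_deg, config.grid_extent_deg,
                       config.grid_points)
    cells = np.array([(gx, gy) for gx in grid for gy in grid])
    rows = []
    t = 2.0  # lead-in so the first epoch fits in the record
    prev = -1
    for cond in config.conditions:
        n = config.events_per_condition
        n_targ = int(round(config.target_fraction * n))
        is_target = np.zeros(n, dtype=bool)
        is_target[rng.choice(n, size=n_targ, replace=False)] = True
        for k in range(n):
            choices = [i for i in range(len(cells)) if i != prev]
            cell = int(rng.choice(choices))
            prev = cell
            rows.append(dict(onset_s=t, stim_x_deg=cells[cell][0],
                             stim_y_deg=cells[cell][1],
                             is_target=bool(is_target[k]), condition=cond))
            t += 1.0
    ev = pd.DataFrame(rows)
    lat = config.saccade_latency + config.saccade_latency_sd * rng.standard_normal(len(ev))
    ev["saccade_onset_s"] = ev["onset_s"] + np.clip(lat, 0.05, 0.6)
    ev["fixation_onset_s"] = ev["saccade_onset_s"] + config.saccade_duration
    ev["land_x_deg"] = ev["stim_x_deg"] + config.landing_noise_deg * rng.standard_normal(len(ev))
    ev["land_y_deg"] = ev["stim_y_deg"] + config.landing_noise_deg * rng.standard_normal(len(ev))
    return ev


def simulate_session(config: SimConfig | None = None, seed: int = 0) -> SimSession:
    """Generate one session; byte-identical for identical (config, seed)."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    head = config.head

    schedule = _event_schedule(config, rng)
    duration = float(schedule["onset_s"].iloc[-1]) + 3.0
    n_eeg = int(round(duration * config.fs_eeg))
    t_eeg = np.arange(n_eeg) / config.fs_eeg
    n_gz = int(round(duration * config.fs_gaze))
    t_gz = np.arange(n_gz) / config.fs_gaze

    start_xy = schedule[["land_x_deg", "land_y_deg"]].iloc[0].to_numpy()
    gx_e, gy_e = _gaze_path(t_eeg, schedule, start_xy, config.saccade_duration)
    gx_g, gy_g = _gaze_path(t_gz, schedule, start_xy, config.saccade_duration)

    fix_onsets = schedule["fixation_onset_s"].to_numpy()
    cond_arr = schedule["condition"].to_numpy()
    targ_arr = schedule["is_target"].to_numpy()

    patterns, activations, names = [], [], []
    for src in config.sources:
        cond_gain = np.array([src.condition_gains.get(c, 1.0) for c in cond_arr])
        if src.kind in ("lambda_burst", "p3_wave"):
            amps = cond_gain * np.where(targ_arr, src.class_gain, 1.0)
            amps = amps * np.exp(config.amplitude_jitter
                                 * rng.standard_normal(len(amps)))
            act = _bump_train(n_eeg, config.fs_eeg,
                              fix_onsets + src.latency, amps, src.width)
            if src.ongoing_sd > 0:
                act = act + src.ongoing_sd * pink_noise(
                    n_eeg, config.fs_eeg, rng)
            patterns.append(_scalp_pattern(src, head))
            activations.append(act)
            names.append(src.name)
        elif src.kind == "background_pink":
            patterns.append(_scalp_pattern(src, head))
            activations.append(pink_noise(n_eeg, config.fs_eeg, rng))
            names.append(src.name)
        elif src.kind == "eog_gaze_linked":
            # moment follows gaze angle: horizontal along x, vertical along z
            for axis, g in (((1.0, 0.0, 0.0), gx_e), ((0.0, 0.0, 1.0), gy_e)):
                pat = _scalp_pattern(src, head, direction=np.asarray(axis))
                patterns.append(pat)
                activations.append(g.copy())
                names.append(f"{src.name}_{'x' if axis[0] else 'y'}")
        elif src.kind == "emg_burst":
            n_bursts = rng.poisson(config.emg_rate_hz * duration)
            act = np.zeros(n_eeg)
            for _ in range(n_bursts):
                c = rng.uniform(1.0, duration - 1.0)
                burst = _band_noise(int(0.3 * config.fs_eeg), config.fs_eeg,
                                    src.band, rng)
                i = int(c * config.fs_eeg)
                act[i:i + burst.size] += burst[: n_eeg - i]
            patterns.append(_scalp_pattern(src, head))
            activations.append(act)
            names.append(src.name)
        else:
            raise ValueError(f"unknown source kind {src.kind!r}")

    P = np.column_stack(patterns)                    # (n_ch, n_src)
    A = np.vstack(activations)                       # (n_src, n_samples)
    eeg = P @ A + config.sensor_noise_uv * rng.standard_normal((head.n_channels, n_eeg))

    # gaze trace at the eye-tracker clock, with measurement noise
    gx = gx_g + config.gaze_noise_deg * rng.standard_normal(n_gz)
    gy = gy_g + config.gaze_noise_deg * rng.standard_normal(n_gz)
    load = np.zeros(n_gz)
    for cond, spans in _condition_spans(schedule).items():
        gain = config.pupil_load_gains.get(cond, 0.0)
        for lo, hi in spans:
            load[(t_gz >= lo) & (t_gz < hi)] = gain
    drift = gaussian_filter1d(rng.standard_normal(n_gz), sigma=2.0 * config.fs_gaze)
    drift = config.pupil_noise * drift / (np.std(drift) + 1e-12)
    pupil = config.pupil_base * (1.0 + load) + drift
    trace = GazeTrace(t=t_gz, x=gx, y=gy, pupil=pupil,
                      valid=np.ones(n_gz, dtype=bool), fs=config.fs_gaze)

    events = schedule[["onset_s", "stim_x_deg", "stim_y_deg", "is_target",
                       "condition", "fixation_onset_s"]].copy()
    truth = dict(
        source_names=names,
        patterns=P.astype(np.float32),
        activations=A.astype(np.float32),
        sources=list(config.sources),
        fixation_onsets=fix_onsets,
        artifact_windows=[],
        duration_s=duration,
    )
    return SimSession(eeg=eeg, fs_eeg=config.fs_eeg, head=head, gaze=trace,
                      events=events, truth=truth)


def _condition_spans(schedule: pd.DataFrame) -> dict[str, list[tuple[float, float]]]:
    out: dict[str, list[tuple[float, float]]] = {}
    for cond in schedule["condition"].unique():
        t = schedule.loc[schedule["condition"] == cond, "onset_s"].to_numpy()
        out[str(cond)] = [(float(t.min()), float(t.max()) + 1.0)]
    return out


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    x /= np.std(x) + 1e-12
    # taper so bursts switch on/off smoothly
    ramp = min(n // 4, int(0.02 * fs))
    win = np.ones(n)
    win[:ramp] = np.linspace(0, 1, ramp)
    win[-ramp:] = np.linspace(1, 0, ramp)
    return x * win


def inject_artifact_bursts(
    eeg: np.ndarray,
    fs: float,
    burst_times: np.ndarray,
    band: tuple[float, float] = (90.0, 120.0),
    amplitude: float = 1.0,
    duration: float = 0.200,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Add band-limited broadband bursts on all channels; return the log.

    ``amplitude`` is the per-channel RMS of the injected burst (same units
    as ``eeg``); zero amplitude leaves the data untouched.  Bursts must
    fit inside the record.
    """
    rng = np.random.default_rng(seed)
    n_ch, n = eeg.shape
    out = eeg.copy()
    rows = []
    for t0 in np.atleast_1d(np.asarray(burst_times, dtype=float)):
        if t0 < 0 or t0 + duration > n / fs:
            raise ValueError("burst outside record duration")
        m = int(round(duration * fs))
        i = int(round(t0 * fs))
        if amplitude != 0.0:
            for c in range(n_ch):
                out[c, i:i + m] += amplitude * _band_noise(m, fs, band, rng)
        rows.append(dict(start_s=t0, end_s=t0 + duration))
    return out, pd.DataFrame(rows, columns=["start_s", "end_s"])
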