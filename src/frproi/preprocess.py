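"""EEG conditioning, high-frequency artifact rejection, and fixation-locked
epoch extraction.

Processing order mirrors a conventional co-registration pipeline:
average-mastoid re-reference, 1 Hz zero-phase high-pass, detection of
broadband-noise windows from 90-120 Hz power (computed at the native
sampling rate, where the band exists comfortably below Nyquist),
downsampling to ``f_s`` = 256 Hz, and a 50 Hz zero-phase low-pass.  The
artifact mask is carried onto the 256 Hz clock and any fixation epoch that
touches a masked sample is discarded.

Epoch grid convention: samples k = -76 ... 255 at 256 Hz, i.e. the
half-open window [-300, 1000) ms around fixation onset — 332 samples of
which exactly 255 are strictly causal (t > 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.signal import butter, resample_poly, sosfiltfilt

#: analysis sampling rate (Hz) after downsampling
FS_ANALYSIS = 256.0

#: default epoch window (s) relative to fixation onset, half-open
EPOCH_WINDOW = (-0.300, 1.000)


@dataclass
class Recording:
    """Continuous multichannel EEG with electrode geometry."""

    data: np.ndarray             # (n_channels, n_samples), microvolts
    fs: float
    channel_names: tuple
    electrode_positions: np.ndarray  # (n_channels, 3) mm
    reference: str = "recording"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names must match data rows")
        if np.asarray(self.electrode_positions).shape[0] != self.data.shape[0]:
            raise ValueError("electrode_positions must match data rows")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ArtifactMask:
    """Per-sample contamination flags plus the flagged-window log."""

    mask: np.ndarray             # bool, length n_samples
    fs: float
    windows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["start_s", "end_s", "zscore"]))

    def resample_to(self, fs_new: float, n_samples: int) -> "ArtifactMask":
        """Map the mask onto another sampling clock (same t=0)."""
        t_new = np.arange(n_samples) / fs_new
        idx = np.clip(np.round(t_new * self.fs).astype(int), 0, self.mask.size - 1)
        return ArtifactMask(mask=self.mask[idx], fs=fs_new, windows=self.windows)

    @property
    def fraction_masked(self) -> float:
        return float(np.mean(self.mask))


@dataclass
class EpochSet:
    """Fixation-locked trials on the fixed [-300, 1000) ms grid."""

    epochs: np.ndarray           # (n_trials, n_series, n_times)
    times: np.ndarray            # s relative to fixation onset
    labels: np.ndarray           # 1 = target, 0 = non-target
    conditions: np.ndarray       # str per trial
    fs: float
    series_kind: str = "channel"  # channel | ic | roi
    series_names: tuple = ()
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.all(np.isin(self.labels, [0, 1])):
            raise ValueError("labels must be 0/1")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def causal(self) -> np.ndarray:
        return self.times > 0

    def select(self, idx: np.ndarray) -> "EpochSet":
        return replace(self, epochs=self.epochs[idx], labels=self.labels[idx],
                       conditions=self.conditions[idx])


def epoch_sample_grid(fs: float = FS_ANALYSIS,
                      window: tuple = EPOCH_WINDOW) -> np.ndarray:
    """Integer sample offsets k with window[0] <= k/fs < window[1]."""
    k_min = math.ceil(window[0] * fs)
    k_max = math.ceil(window[1] * fs) - 1
    return np.arange(k_min, k_max + 1)


# ---------------------------------------------------------------------------
# conditioning


def rereference(rec: Recording, mastoids: tuple = ("M1", "M2"),
                drop: bool = True) -> Recording:
    """Subtract the average of the two mastoid channels from every channel."""
    try:
        idx = [rec.channel_names.index(m) for m in mastoids]
    except ValueError as err:
        raise ValueError(f"mastoid channel missing: {err}") from None
    ref = rec.data[idx].mean(axis=0)
    data = rec.data - ref
    names = rec.channel_names
    pos = np.asarray(rec.electrode_positions)
    if drop:
        keep = [i for i in range(len(names)) if i not in idx]
        data, pos = data[keep], pos[keep]
        names = tuple(names[i] for i in keep)
    return Recording(data=data, fs=rec.fs, channel_names=names,
                     electrode_positions=pos, reference="average-mastoids")


def resample(rec: Recording, fs_new: float = FS_ANALYSIS) -> Recording:
    """Polyphase anti-aliased resampling to ``fs_new`` (<= fs)."""
    if fs_new > rec.fs:
        raise ValueError("upsampling not supported")
    if fs_new == rec.fs:
        return rec
    frac = Fraction(fs_new / rec.fs).limit_denominator(1000)
    data = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1,
                         padtype="line")
    return replace(rec, data=data, fs=fs_new)


def _sos_filter(rec: Recording, cutoff, btype: str, order: int = 4) -> Recording:
    edge = np.max(np.atleast_1d(cutoff))
    if edge >= rec.fs / 2:
        raise ValueError("cutoff at or above Nyquist")
    sos = butter(order, cutoff, btype=btype, fs=rec.fs, output="sos")
    return replace(rec, data=sosfiltfilt(sos, rec.data, axis=1))


def highpass(rec: Recording, cutoff: float = 1.0) -> Recording:
    """Zero-phase 4th-order Butterworth high-pass (applied forward-backward)."""
    return _sos_filter(rec, cutoff, "highpass")


def lowpass(rec: Recording, cutoff: float = 50.0) -> Recording:
    """Zero-phase 4th-order Butterworth low-pass."""
    return _sos_filter(rec, cutoff, "lowpass")


def bandpass_stages(rec: Recording, hp: float = 1.0, lp: float = 50.0,
                    ) -> Recording:
    """High-pass then low-pass, for use when no artifact pass intervenes."""
    return lowpass(highpass(rec, hp), lp)


# ---------------------------------------------------------------------------
# artifact windows


def detect_artifact_windows(
    rec: Recording,
    win: float = 0.100,
    step: float = 0.010,
    band: tuple = (90.0, 120.0),
    k: float = 3.0,
) -> ArtifactMask:
    """Flag sliding windows whose 90-120 Hz power exceeds mean + k*SD.

    Band power per window is the channel-averaged mean square of the
    band-passed signal; window statistics (mean, SD) are computed once
    over all windows of the session.  The mask is the union of flagged
    windows.
    """
    if rec.fs < 2 * band[1]:
        raise ValueError("sampling rate too low for the detector band")
    n = rec.n_samples
    wlen = int(round(win * rec.fs))
    if n < wlen:
        return ArtifactMask(mask=np.zeros(n, dtype=bool), fs=rec.fs)
    sos = butter(4, band, btype="bandpass", fs=rec.fs, output="sos")
    power = sosfiltfilt(sos, rec.data, axis=1) ** 2
    power = power.mean(axis=0)
    csum = np.concatenate([[0.0], np.cumsum(power)])
    starts = np.arange(0, n - wlen + 1, int(round(step * rec.fs)))
    win_power = (csum[starts + wlen] - csum[starts]) / wlen
    mu, sd = win_power.mean(), win_power.std()
    z = (win_power - mu) / sd if sd > 0 else np.zeros_like(win_power)
    flagged = win_power > mu + k * sd
    mask = np.zeros(n, dtype=bool)
    rows = []
    for s, zz in zip(starts[flagged], z[flagged]):
        mask[s:s + wlen] = True
        rows.append(dict(start_s=s / rec.fs, end_s=(s + wlen) / rec.fs,
                         zscore=float(zz)))
    return ArtifactMask(mask=mask, fs=rec.fs,
                        windows=pd.DataFrame(rows, columns=["start_s", "end_s",
                                                            "zscore"]))


# ---------------------------------------------------------------------------
# epochs


def extract_epochs(
    series: np.ndarray,
    fs: float,
    fixation_onsets: np.ndarray,
    labels: np.ndarray,
    conditions: np.ndarray | None = None,
    mask: ArtifactMask | None = None,
    window: tuple = EPOCH_WINDOW,
    series_kind: str = "channel",
    series_names: tuple = (),
) -> EpochSet:
    """Cut fixation-locked epochs on the fixed sample grid.

    Epochs that would run off the record, or that overlap any masked
    sample, are skipped with a log entry.
    """
    series = np.atleast_2d(np.asarray(series))
    n = series.shape[1]
    grid = epoch_sample_grid(fs, window)
    times = grid / fs
    onsets = np.asarray(fixation_onsets, dtype=float)
    labels = np.asarray(labels)
    conditions = (np.asarray(conditions) if conditions is not None
                  else np.array([""] * onsets.size))
    m = mask.mask if mask is not None else None
    if m is not None and m.size != n:
        raise ValueError("mask length must equal number of samples")
    keep_epochs, keep_labels, keep_conds, log = [], [], [], []
    for j, t0 in enumerate(onsets):
        i0 = int(round(t0 * fs))
        sl = i0 + grid
        if sl[0] < 0 or sl[-1] >= n:
            log.append((float(t0), "edge"))
            continue
        if m is not None and m[sl[0]:sl[-1] + 1].any():
            log.append((float(t0), "artifact"))
            continue
        keep_epochs.append(series[:, sl])
        keep_labels.append(labels[j])
        keep_conds.append(conditions[j])
    epochs = (np.stack(keep_epochs) if keep_epochs
              else np.empty((0, series.shape[0], grid.size)))
    return EpochSet(epochs=epochs, times=times,
                    labels=np.asarray(keep_labels, dtype=int),
                    conditions=np.asarray(keep_conds, dtype=object),
                    fs=fs, series_kind=series_kind,
                    series_names=tuple(series_names), log=log)


def subsample_nontargets(epochs: EpochSet, seed: int = 0) -> EpochSet:
    """Balance classes by drawing non-targets down to the target count."""
    rng = np.random.default_rng(seed)
    targ = np.flatnonzero(epochs.labels == 1)
    nont = np.flatnonzero(epochs.labels == 0)
    if nont.size < targ.size:
        raise ValueError("fewer non-targets than targets")
    pick = rng.choice(nont, size=targ.size, replace=False)
    idx = np.sort(np.concatenate([targ, pick]))
    return epochs.select(idx)


def clean_record(rec: Recording, mask: ArtifactMask) -> Recording:
    """Excise masked samples from the continuous record (pre-ICA option)."""
    if mask.mask.size != rec.n_samples:
        raise ValueError("mask length mismatch")
    return replace(rec, data=rec.data[:, ~mask.mask])
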