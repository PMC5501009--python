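"""Morlet continuous wavelet transform and per-epoch spectral power.

The basis follows the Torrence & Compo construction: the mother wavelet is

    psi0(t) = c * pi^(-1/4) * exp(i omega0 t) * exp(-t^2 / 2)

with central frequency ``omega0`` = 6, dilated over 30 geometrically
spaced scales s_j = s0 * 2^(j * dj), s0 = 2/f_s, dj = 0.25.  At
f_s = 256 Hz the equivalent Fourier frequencies span ~0.8-124 Hz; only
bins at or below 32 Hz feed the classifier.

The transform is computed in the frequency domain with unit-energy
normalization per scale (sqrt(2 pi s / dt) on the wavelet spectrum), so
power is comparable across scales.  Epochs are zero-padded to the next
power of two; no cone-of-influence masking is applied — edge effects are
identical across trials and therefore carry no class information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: upper frequency bound (Hz) of the classifier feature view, inclusive
FEATURE_FMAX = 32.0


@dataclass(frozen=True)
class WaveletBasis:
    """30-scale Morlet basis with its equivalent Fourier frequencies."""

    fs: float
    omega0: float
    scales: np.ndarray       # s, geometric with ratio 2^dj
    freqs: np.ndarray        # Hz, decreasing with scale
    dj: float

    @property
    def n_scales(self) -> int:
        return self.scales.size

    def feature_bins(self, fmax: float = FEATURE_FMAX) -> np.ndarray:
        """Indices of scales with Fourier frequency <= fmax."""
        return np.flatnonzero(self.freqs <= fmax)


def fourier_frequency(scale: np.ndarray, omega0: float) -> np.ndarray:
    """Equivalent Fourier frequency of a Morlet wavelet at a given scale."""
    return (omega0 + np.sqrt(2.0 + omega0**2)) / (4.0 * np.pi * scale)


def build_basis(fs: float = 256.0, n: int = 30, dj: float = 0.25,
                omega0: float = 6.0) -> WaveletBasis:
    """Scales s_j = (2/fs) * 2^(j*dj), j = 0..n-1, and their frequencies."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    s0 = 2.0 / fs
    scales = s0 * 2.0 ** (dj * np.arange(n))
    return WaveletBasis(fs=fs, omega0=omega0, scales=scales,
                        freqs=fourier_frequency(scales, omega0), dj=dj)


@dataclass
class TFEpoch:
    """Time-frequency power of one epoch (frequencies x times)."""

    power: np.ndarray        # (n_scales, n_times), >= 0
    freqs: np.ndarray
    times: np.ndarray

    def feature_view(self, fmax: float = FEATURE_FMAX) -> np.ndarray:
        return self.power[self.freqs <= fmax]


def cwt(signal: np.ndarray, basis: WaveletBasis) -> np.ndarray:
    """Complex Morlet CWT along the last axis.

    Parameters
    ----------
    signal : (..., n_times) array
        Real signal(s); NaNs are rejected.

    Returns
    -------
    (..., n_scales, n_times) complex array, linear in the input.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] < 8:
        raise ValueError("signal too short for the wavelet transform")
    if not np.all(np.isfinite(signal)):
        raise ValueError("non-finite samples in signal")
    n = signal.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(n)))
    dt = 1.0 / basis.fs
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, dt)
    fx = np.fft.fft(signal, nfft, axis=-1)                  # (..., nfft)
    # wavelet spectrum per scale, unit-energy normalized
    s = basis.scales[:, None]                               # (n_scales, 1)
    psi_hat = (np.pi ** -0.25) * np.sqrt(2.0 * np.pi * s / dt) * np.exp(
        -0.5 * (s * omega[None, :] - basis.omega0) ** 2
    ) * (omega[None, :] > 0)
    W = np.fft.ifft(fx[..., None, :] * psi_hat, axis=-1)
    return W[..., :n]


def cwt_power(signal: np.ndarray, basis: WaveletBasis,
              times: np.ndarray | None = None) -> TFEpoch:
    """Spectral power |W|^2 = W * conj(W) of one epoch."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("cwt_power expects a single 1-D epoch series")
    W = cwt(signal, basis)
    if times is None:
        times = np.arange(signal.size) / basis.fs
    return TFEpoch(power=(W * W.conj()).real, freqs=basis.freqs, times=times)


def batch_power(signals: np.ndarray, basis: WaveletBasis,
                fmax: float | None = FEATURE_FMAX) -> np.ndarray:
    """Power for a batch of epochs (..., n_times), optionally band-limited.

    Returns (..., n_kept_scales, n_times); the scale axis keeps basis
    order (decreasing frequency) restricted to f <= fmax when given.
    """
    W = cwt(signals, basis)
    p = (W * W.conj()).real
    if fmax is not None:
        p = p[..., basis.feature_bins(fmax), :]
    return p


def feature_vector(tf: TFEpoch, fmax: float = FEATURE_FMAX) -> np.ndarray:
    """Flatten the <= fmax band frequency-major: [f0 all times, f1 ...]."""
    return tf.feature_view(fmax).reshape(-1)
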