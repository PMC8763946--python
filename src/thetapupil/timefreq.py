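"""Morlet wavelet total-power decomposition and dB baseline normalisation.

Power is computed on single trials (total power, capturing phase-locked and
non-phase-locked activity alike) as the squared magnitude of the convolution
with complex Morlet wavelets

    w(t, f) = A exp(-t² / 2σ_t²) exp(2iπft),   A = (σ_t √π)^(-1/2),

where σ_t = c / (2πf) for a cycle count c (default 5).  With the stated A the
wavelet has unit energy, ∫|w|²dt = 1; the discrete convolution is scaled by
the sample period so power values are independent of the sampling rate.
Baseline normalisation is 10·log10(P(t) / mean P over the pre-stimulus
window), i.e. decibels relative to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .eeg_preprocess import EpochSet

__all__ = ["MorletParams", "TFR", "morlet_wavelet", "morlet_decompose", "db_baseline", "band_average"]


@dataclass(frozen=True)
class MorletParams:
    """Wavelet family: frequencies (Hz) and per-frequency cycle count."""

    freqs: tuple[float, ...] = (4.0, 5.0, 6.0, 7.0)
    n_cycles: float = 5.0

    def __post_init__(self) -> None:
        if self.n_cycles < 3:
            raise ValueError("need at least 3 cycles for an admissible wavelet")
        if any(f <= 0 for f in self.freqs):
            raise ValueError("frequencies must be positive")

    def sigma_t(self, f: float) -> float:
        return self.n_cycles / (2.0 * np.pi * f)


@dataclass
class TFR:
    """Time–frequency power: (trials|1, channels, freqs, times)."""

    power: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    sfreq: float
    is_db: bool = False
    meta: object | None = None

    def average(self) -> "TFR":
        return replace(self, power=self.power.mean(axis=0, keepdims=True))


def morlet_wavelet(f: float, sfreq: float, n_cycles: float = 5.0) -> np.ndarray:
    """Complex Morlet wavelet sampled at ``sfreq``, scaled by the sample period.

    Support is ±5σ_t so the Gaussian tail is negligible at the edges.
    """
    sigma = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(5.0 * sigma * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    a = (sigma * np.sqrt(np.pi)) ** -0.5
    w = a * np.exp(-(t**2) / (2.0 * sigma**2)) * np.exp(2j * np.pi * f * t)
    return w / sfreq  # discrete convolution ≈ continuous integral


def morlet_decompose(
    ep: EpochSet, params: MorletParams = MorletParams(), average: bool = False
) -> TFR:
    """Single-trial total wavelet power of an epoch set.

    The lowest frequency must complete its wavelet support inside the epoch
    (cone-of-influence guard).  Set ``average=True`` to return trial-averaged
    power.
    """
    freqs = np.asarray(params.freqs, float)
    if freqs.max() >= ep.sfreq / 2:
        raise ValueError("frequencies must lie below the Nyquist frequency")
    n_t = ep.data.shape[-1]
    for f in freqs:
        if 2 * int(np.ceil(5 * params.sigma_t(f) * ep.sfreq)) + 1 > n_t:
            raise ValueError(f"epoch too short for wavelet at {f} Hz")
    power = np.empty(ep.data.shape[:2] + (freqs.size, n_t))
    for k, f in enumerate(freqs):
        w = morlet_wavelet(f, ep.sfreq, params.n_cycles)
        conv = fftconvolve(ep.data, w[None, None, :], mode="same", axes=2)
        power[:, :, k, :] = np.abs(conv) ** 2
    tfr = TFR(power=power, times=ep.times, freqs=freqs, sfreq=ep.sfreq, meta=ep.meta)
    return tfr.average() if average else tfr


def db_baseline(tfr: TFR, window: tuple[float, float] = (-0.2, 0.0)) -> TFR:
    """Convert raw power to dB relative to the mean over ``window``."""
    if tfr.is_db:
        raise ValueError("power is already in dB")
    sl = (tfr.times >= window[0]) & (tfr.times < window[1])
    if not sl.any():
        raise ValueError("baseline window contains no samples")
    base = tfr.power[..., sl].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline power must be positive")
    return replace(tfr, power=10.0 * np.log10(tfr.power / base), is_db=True)


def db_invert(tfr: TFR, window: tuple[float, float] = (-0.2, 0.0), baseline_power: np.ndarray | None = None) -> TFR:
    """Invert :func:`db_baseline` given the original baseline power."""
    if not tfr.is_db:
        raise ValueError("power is not in dB")
    if baseline_power is None:
        raise ValueError("need the baseline power to invert a dB transform")
    return replace(tfr, power=10.0 ** (tfr.power / 10.0) * baseline_power, is_db=False)


def band_average(
    tfr: TFR,
    band: tuple[float, float] = (4.0, 7.0),
    window: tuple[float, float] | None = None,
    channels: list[str] | None = None,
    ch_names: list[str] | None = None,
) -> np.ndarray:
    """Average power over a frequency band (and optionally channels/time).

    ``channels`` selects an electrode set by name (requires ``ch_names``);
    with ``window`` the result is additionally averaged over that interval.
    Returns (trials, channels, times), (trials, times) when channels are
    averaged, reduced further over time when ``window`` is given.
    """
    fmask = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    if not fmask.any():
        raise ValueError("band does not overlap the computed frequencies")
    out = tfr.power[:, :, fmask, :].mean(axis=2)
    if channels is not None:
        if ch_names is None:
            raise ValueError("channel selection needs ch_names")
        idx = [ch_names.index(c) for c in channels]
        out = out[:, idx, :].mean(axis=1)
    if window is not None:
        tmask = (tfr.times >= window[0]) & (tfr.times <= window[1])
        out = out[..., tmask].mean(axis=-1)
    return out
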