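"""Conventional single-channel spectral comparators.

Three indices computed from one channel (clinically, the prefrontal
Fp1): the 95% spectral edge frequency, band-limited spectral entropy
(0.8-47 Hz) and synch fast slow (a bispectral fast/slow log ratio).
Spectra come from Welch averaging: 2 s Hann segments, 50% overlap.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "welch_spectrum",
    "sef",
    "sef_from_psd",
    "spectral_entropy",
    "spectral_entropy_from_psd",
    "sfs",
]


def welch_spectrum(
    x: np.ndarray, fs: float, segment_s: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with Hann taper and 50% overlap."""
    x = np.asarray(x, dtype=float)
    nperseg = min(int(round(segment_s * fs)), len(x))
    return signal.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return (freqs >= lo) & (freqs <= hi)


def sef_from_psd(
    freqs: np.ndarray,
    power: np.ndarray,
    quantile: float = 0.95,
    band: tuple[float, float] | None = None,
) -> float:
    """Spectral edge of a given PSD: lowest f with >= quantile of in-band power."""
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    if band is None:
        band = (float(freqs[0]), float(freqs[-1]))
    mask = _band_mask(freqs, band)
    p = power[mask]
    total = p.sum()
    if total <= 0:
        raise ValueError("zero in-band power")
    cum = np.cumsum(p) / total
    i = min(int(np.searchsorted(cum, quantile)), len(cum) - 1)
    return float(freqs[mask][i])


def sef(
    x: np.ndarray,
    fs: float,
    quantile: float = 0.95,
    band: tuple[float, float] | None = None,
) -> float:
    """Spectral edge frequency of a signal window (Welch PSD)."""
    freqs, power = welch_spectrum(x, fs)
    if band is None:
        band = (0.0, fs / 2)
    if not 0 <= band[0] < band[1] <= fs / 2:
        raise ValueError(f"band {band} outside [0, Nyquist]")
    return sef_from_psd(freqs, power, quantile, band)


def spectral_entropy_from_psd(
    freqs: np.ndarray, power: np.ndarray, band: tuple[float, float]
) -> float:
    """Normalized Shannon entropy of an in-band power distribution, in [0, 1]."""
    p = power[_band_mask(freqs, band)]
    total = p.sum()
    if total <= 0 or len(p) < 2:
        raise ValueError("zero in-band power or too few bins")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(p)))


def spectral_entropy(
    x: np.ndarray, fs: float, band: tuple[float, float] = (0.8, 47.0)
) -> float:
    """Band-limited spectral entropy of a signal window (Welch PSD)."""
    freqs, power = welch_spectrum(x, fs)
    if not 0 <= band[0] < band[1] <= fs / 2:
        raise ValueError(f"band {band} outside [0, Nyquist]")
    return spectral_entropy_from_psd(freqs, power, band)


def _bispectrum(x: np.ndarray, fs: float, segment_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Segment-averaged bispectrum magnitude |mean_k X(f1) X(f2) X*(f1+f2)|."""
    x = np.asarray(x, dtype=float)
    nper = int(round(segment_s * fs))
    if len(x) < 2 * nper:
        raise ValueError(f"window too short for bispectral averaging (< {2 * segment_s} s)")
    step = nper // 2
    n_seg = (len(x) - nper) // step + 1
    taper = np.hanning(nper)
    half = nper // 2 + 1
    acc = np.zeros((half, half), dtype=complex)
    idx = np.arange(half)
    pair_sum = idx[:, None] + idx[None, :]
    valid = pair_sum < half
    pair_sum = np.where(valid, pair_sum, 0)
    for k in range(n_seg):
        seg = x[k * step : k * step + nper]
        seg = (seg - seg.mean()) * taper
        X = np.fft.rfft(seg)
        acc += np.outer(X, X) * np.conj(X[pair_sum]) * valid
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    return freqs, np.abs(acc / n_seg)


def _region_sum(
    freqs: np.ndarray, bispec: np.ndarray, band: tuple[float, float]
) -> float:
    """Sum of bispectral magnitude over pairs f2 <= f1 with f1+f2 in band."""
    f1 = freqs[:, None]
    f2 = freqs[None, :]
    fsum = f1 + f2
    region = (f2 <= f1) & (f1 > 0) & (f2 > 0) & (fsum >= band[0]) & (fsum <= band[1])
    return float(bispec[region].sum())


def sfs(
    x: np.ndarray,
    fs: float,
    fast_band: tuple[float, float] = (40.0, 47.0),
    full_band: tuple[float, float] = (0.5, 47.0),
    segment_s: float = 2.0,
) -> float:
    """Synch fast slow: log10 of fast-band over full-band bispectral sums.

    Scale-invariant (the cubic amplitude dependence of the bispectrum
    cancels in the ratio); 0 when the two regions coincide.
    """
    freqs, bispec = _bispectrum(x, fs, segment_s)
    num = _region_sum(freqs, bispec, fast_band)
    den = _region_sum(freqs, bispec, full_band)
    if den <= 0 or num <= 0:
        raise ValueError("empty bispectral region sum")
    return float(np.log10(num / den))
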