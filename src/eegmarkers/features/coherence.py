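"""Continuous wavelet transform and wavelet coherence between channels.

The CWT is computed as the discrete correlation

    C(a, b) = (1/sqrt(a)) * sum_t x(t) * conj(Psi((t - b) / a)),

with the analytic Morlet mother wavelet
``Psi(u) = pi**(-1/4) * exp(i w0 u) * exp(-u**2 / 2)`` (w0 = 6), scales
expressed in samples and the kernel truncated at |u| = 6 where the
Gaussian envelope is negligible. The scale-to-frequency map is
``f = w0 * fs / (2 pi a)``.

The raw normalised cross-spectrum has unit modulus pointwise, so the
cross- and auto-spectra are smoothed before taking the ratio -- a
Gaussian kernel in time whose width tracks the scale (0.6 * a) and a
5-point moving average across scales. Coherence

    coh(a, b) = |S(Cx Cy*)| / sqrt(S(|Cx|^2) S(|Cy|^2))

then lies in [0, 1] by the Cauchy-Schwarz inequality, equals 1
identically for y = +/- x, and drops toward the smoothing-limited noise
floor for independent signals. A single scalar per channel pair is the
mean of the coherence over the 0.5-30 Hz time-scale plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import fftconvolve

__all__ = ["CwtField", "morlet_wavelet", "morlet_scales", "cwt",
           "wavelet_coherence"]

OMEGA0 = 6.0
_TRUNC = 6.0        # kernel support: |u| <= _TRUNC
_TIME_SMOOTH = 0.6  # time-smoothing std in units of the scale
_SCALE_SMOOTH = 5   # moving-average window across scales


def morlet_wavelet(u: np.ndarray, omega0: float = OMEGA0) -> np.ndarray:
    """Morlet mother wavelet sampled at dimensionless argument ``u``."""
    return np.pi ** -0.25 * np.exp(1j * omega0 * u) * np.exp(-0.5 * u ** 2)


def morlet_scales(fs: float = 128.0, fmin: float = 0.5, fmax: float = 30.0,
                  n_per_octave: int = 6, omega0: float = OMEGA0) -> np.ndarray:
    """Log-spaced scales (in samples) covering [fmin, fmax] Hz."""
    if fmin <= 0 or fmax <= fmin:
        raise ValueError("need 0 < fmin < fmax")
    a_min = omega0 * fs / (2.0 * np.pi * fmax)
    a_max = omega0 * fs / (2.0 * np.pi * fmin)
    n = int(np.ceil(np.log2(a_max / a_min) * n_per_octave)) + 1
    return a_min * 2.0 ** (np.arange(n) / n_per_octave)


@dataclass
class CwtField:
    """Complex CWT coefficients over a strictly increasing scale grid."""

    coefficients: np.ndarray  # (n_scales, T) complex
    scales: np.ndarray        # samples
    fs: float
    omega0: float = OMEGA0

    @property
    def frequencies(self) -> np.ndarray:
        """Centre frequency (Hz) of each scale."""
        return self.omega0 * self.fs / (2.0 * np.pi * self.scales)


def cwt(series: np.ndarray, scales: np.ndarray, fs: float = 128.0,
        omega0: float = OMEGA0) -> CwtField:
    """Morlet CWT of a series over the given scale grid (in samples)."""
    x = np.asarray(series, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if scales.size == 0:
        raise ValueError("empty scale grid")
    if np.any(np.diff(scales) <= 0):
        raise ValueError("scales must be strictly increasing")
    T = len(x)
    out = np.empty((len(scales), T), dtype=complex)
    for s, a in enumerate(scales):
        half = int(np.ceil(_TRUNC * a))
        n = np.arange(-half, half + 1)
        # correlation kernel g[n] = (1/sqrt(a)) * conj(Psi(-n/a))
        kernel = np.conj(morlet_wavelet(-n / a, omega0)) / np.sqrt(a)
        out[s] = fftconvolve(x, kernel, mode="same")
    return CwtField(coefficients=out, scales=scales, fs=fs, omega0=omega0)


def _smooth(field: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Scale-matched Gaussian smoothing in time, then across scales."""
    out = np.empty_like(field)
    for s, a in enumerate(scales):
        sigma = max(_TIME_SMOOTH * a, 1.0)
        half = int(np.ceil(4.0 * sigma))
        t = np.arange(-half, half + 1)
        kernel = np.exp(-0.5 * (t / sigma) ** 2)
        kernel /= kernel.sum()
        out[s] = fftconvolve(field[s], kernel, mode="same")
    if np.iscomplexobj(field):
        re = uniform_filter1d(out.real, _SCALE_SMOOTH, axis=0, mode="nearest")
        im = uniform_filter1d(out.imag, _SCALE_SMOOTH, axis=0, mode="nearest")
        return re + 1j * im
    return uniform_filter1d(out, _SCALE_SMOOTH, axis=0, mode="nearest")


def wavelet_coherence(x: np.ndarray, y: np.ndarray, fs: float = 128.0,
                      scales: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, float]:
    """Wavelet coherence map in [0, 1] and its time-scale mean.

    Accepts precomputed :class:`CwtField` objects in place of raw
    series, which avoids recomputing transforms when a channel appears
    in many pairs.
    """
    if scales is None:
        scales = morlet_scales(fs)
    if isinstance(x, CwtField):
        cx = x
    else:
        x = np.asarray(x, dtype=float)
        if np.std(x) == 0:
            raise ValueError("constant input: auto-spectrum is zero")
        cx = cwt(x, scales, fs)
    if isinstance(y, CwtField):
        cy = y
    else:
        y = np.asarray(y, dtype=float)
        if np.std(y) == 0:
            raise ValueError("constant input: auto-spectrum is zero")
        cy = cwt(y, scales, fs)
    if cx.coefficients.shape != cy.coefficients.shape:
        raise ValueError("series lengths (or scale grids) differ")
    Wx = cx.coefficients
    Wy = cy.coefficients
    s_xy = _smooth(Wx * np.conj(Wy), scales)
    s_xx = _smooth(np.abs(Wx) ** 2, scales)
    s_yy = _smooth(np.abs(Wy) ** 2, scales)
    denom = np.sqrt(np.maximum(s_xx, 0.0) * np.maximum(s_yy, 0.0))
    if np.all(denom == 0):
        raise ValueError("constant input: auto-spectrum is zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(s_xy) / denom, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    return coh, float(coh.mean())
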