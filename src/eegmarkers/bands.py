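"""Dyadic wavelet decomposition of EEG into the canonical rhythm bands.

Each channel is decomposed with the orthogonal Daubechies-4 wavelet
(four vanishing moments, ``db4`` in PyWavelets naming) using periodized
boundary handling, which makes the transform exactly orthogonal: the
coefficient count equals the sample count and energy is conserved. At 128 Hz a 4-level decomposition
maps the dyadic sub-bands onto the named rhythms::

    d1  32-64 Hz   (discarded: signals are band-limited to 0.5-30 Hz)
    d2  16-32 Hz   beta
    d3   8-16 Hz   alpha
    d4    4-8 Hz   theta
    a4    0-4 Hz   delta

The dyadic edges differ slightly from the conventional printed ranges
(15-30, 8-15 Hz); they are the only edges consistent with a dyadic
transform. Band signals are reconstructed by zeroing every other
coefficient set and inverting, so the four band signals plus the
discarded d1 reconstruction sum to the original signal exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = ["WAVELET", "LEVELS", "BAND_TO_SET", "BANDS_WITH_ORIGINAL",
           "BandDecomposition", "dwt_decompose", "extract_band",
           "reconstruct_set"]

WAVELET = "db4"      # orthogonal Daubechies wavelet, 4 vanishing moments
MODE = "periodization"
LEVELS = 4           # J: dyadic levels at fs = 128 Hz

#: Band name -> coefficient-set label at fs = 128 Hz, J = 4.
BAND_TO_SET: dict[str, str] = {
    "delta": "a4", "theta": "d4", "alpha": "d3", "beta": "d2",
}

#: All J + 1 coefficient-set labels, coarsest first.
SET_LABELS: tuple[str, ...] = ("a4", "d4", "d3", "d2", "d1")

#: Band choices accepted throughout the analysis layers.
BANDS_WITH_ORIGINAL: tuple[str, ...] = ("original", "delta", "theta",
                                        "alpha", "beta")


@dataclass
class BandDecomposition:
    """Coefficient sets of one channel's J-level decomposition.

    ``coeffs`` is the PyWavelets ``wavedec`` list ``[aJ, dJ, ..., d1]``.
    """

    coeffs: list[np.ndarray]
    n_samples: int
    wavelet: str = WAVELET
    levels: int = LEVELS

    @property
    def set_labels(self) -> tuple[str, ...]:
        J = self.levels
        return ("a%d" % J,) + tuple("d%d" % j for j in range(J, 0, -1))

    def coefficient_set(self, label: str) -> np.ndarray:
        try:
            idx = self.set_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown coefficient set {label!r}") from None
        return self.coeffs[idx]

    def energies(self) -> dict[str, float]:
        """Sum of squared coefficients per set."""
        return {lab: float(np.sum(c ** 2))
                for lab, c in zip(self.set_labels, self.coeffs)}

    def reconstruct(self, label: str) -> np.ndarray:
        """Invert the transform keeping only one coefficient set."""
        kept = [c if self.set_labels[i] == label else np.zeros_like(c)
                for i, c in enumerate(self.coeffs)]
        out = pywt.waverec(kept, self.wavelet, mode=MODE)
        return out[: self.n_samples]


def dwt_decompose(series: np.ndarray, levels: int = LEVELS,
                  wavelet: str = WAVELET) -> BandDecomposition:
    """J-level orthogonal DWT with periodized boundaries.

    Requires the series length to be divisible by ``2**levels`` so the
    coefficient counts halve exactly and energy is conserved.
    """
    x = np.asarray(series, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(x) % (2 ** levels) != 0:
        raise ValueError(
            f"series length {len(x)} not divisible by 2**{levels}"
        )
    coeffs = pywt.wavedec(x, wavelet, mode=MODE, level=levels)
    return BandDecomposition(coeffs=coeffs, n_samples=len(x),
                             wavelet=wavelet, levels=levels)


def reconstruct_set(series: np.ndarray, label: str) -> np.ndarray:
    """Reconstruction of one coefficient set of the default decomposition."""
    return dwt_decompose(series).reconstruct(label)


def extract_band(series: np.ndarray, band: str, fs: float = 128.0) -> np.ndarray:
    """Band-limited signal for one named rhythm (delta/theta/alpha/beta).

    Only defined for the study's sampling rate of 128 Hz, where the
    4-level dyadic sub-bands line up with the rhythm definitions.
    """
    if band not in BAND_TO_SET:
        raise ValueError(
            f"unknown band {band!r}; expected one of {sorted(BAND_TO_SET)}"
        )
    if fs != 128.0:
        raise ValueError("band extraction is defined for fs = 128 Hz")
    return dwt_decompose(series).reconstruct(BAND_TO_SET[band])
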