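"""Relative wavelet energy of the dyadic coefficient sets.

The relative energy of band ``j`` is the fraction of the total squared
wavelet-coefficient energy carried by that band's coefficient set. The
transform is orthogonal, so the J+1 relative energies sum to 1, and an
"original" (unfiltered) signal -- whose numerator is the whole
decomposition -- always scores exactly 1, making the measure
non-discriminative on raw signals by construction.
"""

from __future__ import annotations

import numpy as np

from ..bands import BAND_TO_SET, dwt_decompose

__all__ = ["relative_wavelet_energy", "band_energy_fractions"]


def band_energy_fractions(series: np.ndarray) -> dict[str, float]:
    """Relative energy of every coefficient set (a4, d4, d3, d2, d1)."""
    dec = dwt_decompose(series)
    energies = dec.energies()
    total = sum(energies.values())
    if total == 0:
        raise ValueError("zero-energy signal: relative energy undefined")
    return {lab: e / total for lab, e in energies.items()}


def relative_wavelet_energy(series: np.ndarray, band: str = "original") -> float:
    """Relative energy of one rhythm band, or 1.0 for ``band='original'``."""
    fractions = band_energy_fractions(series)
    if band == "original":
        return float(sum(fractions.values()))
    if band not in BAND_TO_SET:
        raise ValueError(f"unknown band {band!r}")
    return float(fractions[BAND_TO_SET[band]])
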