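"""Katz fractal dimension of a waveform.

The waveform is treated as a planar curve with unit abscissa steps.
With curve length ``D`` (sum of adjacent-point distances), maximal
extent ``d`` (largest distance from the first point to any other) and
``T`` samples, the dimension is

    F = ln(T - 1) / ln(d * (T - 1) / D).

Any straight line gives exactly 1; rougher waveforms give larger values.
"""

from __future__ import annotations

import numpy as np

__all__ = ["katz_fd"]


def katz_fd(series: np.ndarray) -> float:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("series must be 1-D with at least 3 samples")
    T = len(x)
    dx = np.diff(x)
    D = float(np.sum(np.hypot(1.0, dx)))
    i = np.arange(T)
    d = float(np.max(np.hypot(i, x - x[0])))
    ratio = d * (T - 1) / D
    if ratio <= 0 or np.isclose(ratio, 1.0):
        raise ValueError("degenerate waveform: d*(T-1)/D is 1, dimension undefined")
    return float(np.log(T - 1) / np.log(ratio))
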