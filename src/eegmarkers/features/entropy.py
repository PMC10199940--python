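"""Quadratic entropy: a tolerance-corrected sample entropy.

Template matching follows the sample-entropy convention: length-``m``
templates are compared under the Chebyshev distance, self-matches are
excluded, and only templates whose length-``(m+1)`` extension exists are
counted, so the length-``m`` and length-``(m+1)`` match counts run over
the same index set. With total match counts ``B`` (length m) and ``A``
(length m+1),

    E = -ln(A / B),        Q = E + ln(2 r).

The ``+ ln(2r)`` correction removes most of the tolerance dependence of
``E``; the tolerance ``r`` is expressed in units of the series' standard
deviation (the series is z-scored before matching), so Q is invariant
under shifting and scaling of the input.

A constant series matches everywhere, giving E = 0 and Q = ln(2r).
When no template pair matches at length m (or none extends to length
m+1) the entropy is undefined and :class:`EntropyUndefined` is raised.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EntropyUndefined", "quadratic_entropy", "match_counts", "entropy_profile"]

_BLOCK = 512  # row-block size for the pairwise distance computation


class EntropyUndefined(ValueError):
    """No template matches at the required length; entropy is undefined."""


def _scaled(series: np.ndarray) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    sd = x.std()
    return x / sd if sd > 0 else x


def match_counts(series: np.ndarray, m: int, r: float,
                 scale: bool = True) -> tuple[int, int]:
    """Ordered-pair match counts (B at length m, A at length m+1).

    Counts pairs ``i != j`` over the ``T - m`` templates whose
    length-(m+1) extension exists; blocked so memory stays O(T * block).
    """
    if r <= 0:
        raise ValueError("tolerance r must be > 0")
    if m < 1:
        raise ValueError("template length m must be >= 1")
    y = _scaled(series) if scale else np.asarray(series, dtype=float)
    n = len(y) - m
    if n < 2:
        raise ValueError("series too short for template length m")
    B = 0
    A = 0
    for start in range(0, n, _BLOCK):
        stop = min(start + _BLOCK, n)
        rows = stop - start
        d_m = np.zeros((rows, n))
        for lag in range(m):
            d_m = np.maximum(d_m, np.abs(
                y[start + lag: stop + lag, None] - y[lag: n + lag][None, :]
            ))
        b = d_m <= r
        d_m1 = np.maximum(d_m, np.abs(
            y[start + m: stop + m, None] - y[m: n + m][None, :]
        ))
        a = d_m1 <= r
        # remove self-matches on the diagonal of the full matrix
        diag = np.arange(start, stop)
        b[np.arange(rows), diag] = False
        a[np.arange(rows), diag] = False
        B += int(b.sum())
        A += int(a.sum())
    return B, A


def quadratic_entropy(series: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Quadratic entropy Q = -ln(A/B) + ln(2r), with r in SD units."""
    B, A = match_counts(series, m, r)
    if B == 0 or A == 0:
        raise EntropyUndefined(
            f"no template matches at m={m}, r={r}; entropy undefined"
        )
    return float(-np.log(A / B) + np.log(2.0 * r))


def entropy_profile(series: np.ndarray, m: int,
                    rs: np.ndarray) -> dict[float, float | None]:
    """Quadratic entropy over a grid of tolerances in one pass.

    Computes the pairwise template distances once and counts matches for
    every tolerance by binary search; grid points where the entropy is
    undefined map to ``None``. Intended for parameter scans.
    """
    y = _scaled(series)
    n = len(y) - m
    if n < 2:
        raise ValueError("series too short for template length m")
    d_m_all = []
    d_m1_all = []
    for start in range(0, n, _BLOCK):
        stop = min(start + _BLOCK, n)
        rows = stop - start
        d_m = np.zeros((rows, n))
        for lag in range(m):
            d_m = np.maximum(d_m, np.abs(
                y[start + lag: stop + lag, None] - y[lag: n + lag][None, :]
            ))
        d_m1 = np.maximum(d_m, np.abs(
            y[start + m: stop + m, None] - y[m: n + m][None, :]
        ))
        diag = np.arange(start, stop)
        d_m[np.arange(rows), diag] = np.inf
        d_m1[np.arange(rows), diag] = np.inf
        d_m_all.append(d_m.ravel())
        d_m1_all.append(d_m1.ravel())
    dm = np.sort(np.concatenate(d_m_all))
    dm1 = np.sort(np.concatenate(d_m1_all))
    out: dict[float, float | None] = {}
    for r in np.asarray(rs, dtype=float):
        B = int(np.searchsorted(dm, r, side="right"))
        A = int(np.searchsorted(dm1, r, side="right"))
        if B == 0 or A == 0:
            out[float(r)] = None
        else:
            out[float(r)] = float(-np.log(A / B) + np.log(2.0 * r))
    return out
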