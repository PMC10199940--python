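"""Computational-cost curves: wall-time of each measure vs. series length.

Each measure is timed on freshly generated white noise over a grid of
lengths (default 500 to 10,000 in steps of 100, 96 points), taking the
median over repeats; the curve is normalised by the time at the first
grid point, and a log-log straight-line fit gives an empirical scaling
exponent. Absolute wall-times are hardware-dependent; the informative
outputs are the normalised curves and their ordering (the visibility
graph, with its T x T adjacency, is the most expensive measure at large
T).

Timing uses fixed measure parameters: m = 2, r = 0.2 for the entropy,
Q = round(2 T^(1/3)) and k = 1 for the quantile graph; coherence
receives two independent noise series.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .features.coherence import morlet_scales, wavelet_coherence
from .features.energy import band_energy_fractions
from .features.entropy import quadratic_entropy
from .features.fractal import katz_fd
from .features.graphs import (build_quantile_graph, build_visibility_graph,
                              complexity_index, default_quantile_count,
                              mean_jump_length)
from .synthetic import white_noise

__all__ = ["CostCurve", "cost_curve", "default_length_grid", "BENCH_MEASURES"]


def default_length_grid() -> np.ndarray:
    """The study grid: T = 500, 600, ..., 10,000 (96 points)."""
    return np.arange(500, 10_001, 100)


def _run_wc(x: np.ndarray, y: np.ndarray) -> None:
    wavelet_coherence(x, y, fs=128.0, scales=morlet_scales(128.0))


def _run_qe(x: np.ndarray, y: np.ndarray) -> None:
    quadratic_entropy(x, m=2, r=0.2)


def _run_we(x: np.ndarray, y: np.ndarray) -> None:
    band_energy_fractions(_pad_pow16(x))


def _pad_pow16(x: np.ndarray) -> np.ndarray:
    # the dyadic decomposition needs a multiple of 2**4
    cut = len(x) - len(x) % 16
    return x[:cut]


def _run_fd(x: np.ndarray, y: np.ndarray) -> None:
    katz_fd(x)


def _run_qg(x: np.ndarray, y: np.ndarray) -> None:
    graph = build_quantile_graph(x, default_quantile_count(len(x)), 1)
    mean_jump_length(graph)


def _run_vg(x: np.ndarray, y: np.ndarray) -> None:
    complexity_index(build_visibility_graph(x))


BENCH_MEASURES = {
    "wc": _run_wc, "fd": _run_fd, "qe": _run_qe,
    "we": _run_we, "qg": _run_qg, "vg": _run_vg,
}


@dataclass
class CostCurve:
    """Wall-time of one measure across series lengths."""

    measure: str
    lengths: np.ndarray
    times: np.ndarray        # median wall-time in seconds
    normalized: np.ndarray   # times / times[0]
    exponent: float          # slope of log(time) vs log(T)


def cost_curve(measures=("wc", "fd", "qe", "we", "qg", "vg"), seed: int = 0,
               repeats: int = 3,
               lengths: np.ndarray | None = None) -> list[CostCurve]:
    """Time each measure on white noise across the length grid."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if lengths is None:
        lengths = default_length_grid()
    lengths = np.asarray(lengths, dtype=int)
    unknown = [m for m in measures if m not in BENCH_MEASURES]
    if unknown:
        raise ValueError(f"unregistered measures: {unknown}")
    curves = []
    counter = int(seed)
    for measure in measures:
        run = BENCH_MEASURES[measure]
        # warm-up outside the timed region (caches, lazy imports)
        run(white_noise(int(lengths[0]), counter), white_noise(int(lengths[0]), counter + 1))
        times = np.empty(len(lengths))
        for i, T in enumerate(lengths):
            samples = []
            for _ in range(repeats):
                x = white_noise(int(T), counter)
                y = white_noise(int(T), counter + 1)
                counter += 2
                t0 = time.perf_counter()
                run(x, y)
                samples.append(time.perf_counter() - t0)
            times[i] = float(np.median(samples))
        normalized = times / times[0]
        slope = np.polyfit(np.log(lengths), np.log(times), 1)[0]
        curves.append(CostCurve(measure=measure, lengths=lengths,
                                times=times, normalized=normalized,
                                exponent=float(slope)))
    return curves
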