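"""Tidy feature extraction: one value per (subject, electrode, band, measure).

Six measures are supported, identified by short codes:

    wc  wavelet coherence (per electrode pair; scalar = plane mean)
    fd  Katz fractal dimension
    qe  quadratic entropy (parameters m, r)
    we  relative wavelet energy of the band
    qg  quantile-graph mean jump length (parameters Q, k)
    vg  visibility-graph complexity index

Every measure can be computed on the original signal or on one of the
four reconstructed rhythm bands. Coherence rows carry an electrode-pair
label ("T3-O2"); :func:`electrode_coherence` folds pair values into a
per-electrode value by averaging over the 18 pairs containing each
electrode.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from ..bands import extract_band
from .coherence import cwt, morlet_scales, wavelet_coherence
from .energy import relative_wavelet_energy
from .entropy import EntropyUndefined, quadratic_entropy
from .fractal import katz_fd
from .graphs import (build_quantile_graph, build_visibility_graph,
                     complexity_index, default_quantile_count,
                     mean_jump_length)

__all__ = ["MEASURES", "SERIES_MEASURES", "compute_series_measure",
           "extract_features", "electrode_coherence"]

MEASURES: tuple[str, ...] = ("wc", "fd", "qe", "we", "qg", "vg")
#: Measures of a single series (all but the pairwise coherence).
SERIES_MEASURES: tuple[str, ...] = ("fd", "qe", "we", "qg", "vg")

FEATURE_COLUMNS = ["subject_id", "group", "electrode", "band",
                   "measure", "params", "value"]


def compute_series_measure(series: np.ndarray, measure: str, *,
                           band: str = "original",
                           m: int = 2, r: float = 0.2,
                           Q: int | None = None, k: int = 1) -> float:
    """One scalar measure of one (possibly band-filtered) series."""
    if measure == "fd":
        return katz_fd(series)
    if measure == "qe":
        return quadratic_entropy(series, m=m, r=r)
    if measure == "we":
        return relative_wavelet_energy(series, band)
    if measure == "qg":
        if Q is None:
            Q = default_quantile_count(len(series))
        return mean_jump_length(build_quantile_graph(series, Q, k))
    if measure == "vg":
        return complexity_index(build_visibility_graph(series))
    raise ValueError(f"unknown series measure {measure!r}")


def _params_label(measure: str, m: int, r: float, Q: int, k: int) -> str:
    if measure == "qe":
        return f"m={m},r={r:g}"
    if measure == "qg":
        return f"Q={Q},k={k}"
    return ""


def _band_signal(record, channel: str, band: str) -> np.ndarray:
    x = record.channel(channel)
    return x if band == "original" else extract_band(x, band, record.fs)


def extract_features(records, measures=SERIES_MEASURES,
                     bands=("original",), *,
                     m: int = 2, r: float = 0.2,
                     Q: int | None = None, k: int = 1,
                     coherence_pairs: list[tuple[str, str]] | None = None,
                     ) -> pd.DataFrame:
    """Feature table for a list of records.

    ``we`` is skipped for ``band='original'`` (identically 1) unless it
    is the only requested measure; undefined entropy values are skipped.
    For ``wc``, ``coherence_pairs`` restricts the electrode pairs
    (default: all pairs).
    """
    rows = []
    measures = tuple(measures)
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures {sorted(unknown)}")
    for record in records:
        T = record.n_samples
        q_eff = Q if Q is not None else default_quantile_count(T)
        for band in bands:
            band_signals = {ch: _band_signal(record, ch, band)
                            for ch in record.channel_names}
            for measure in measures:
                if measure == "wc":
                    rows.extend(_coherence_rows(record, band, band_signals,
                                                coherence_pairs))
                    continue
                params = _params_label(measure, m, r, q_eff, k)
                for ch in record.channel_names:
                    # relative energy takes the raw series; its band is the
                    # numerator coefficient set, not an input filter
                    sig = (record.channel(ch) if measure == "we"
                           else band_signals[ch])
                    try:
                        value = compute_series_measure(
                            sig, measure, band=band,
                            m=m, r=r, Q=q_eff, k=k)
                    except EntropyUndefined:
                        continue
                    rows.append((record.subject_id, record.group, ch,
                                 band, measure, params, value))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def _coherence_rows(record, band, band_signals, pairs):
    scales = morlet_scales(record.fs)
    names = record.channel_names
    if pairs is None:
        pairs = list(itertools.combinations(names, 2))
    needed = sorted({ch for p in pairs for ch in p}, key=names.index)
    fields = {ch: cwt(band_signals[ch], scales, record.fs) for ch in needed}
    rows = []
    for ch_a, ch_b in pairs:
        _, summary = wavelet_coherence(fields[ch_a], fields[ch_b], record.fs,
                                       scales=scales)
        rows.append((record.subject_id, record.group, f"{ch_a}-{ch_b}",
                     band, "wc", "", summary))
    return rows


def electrode_coherence(table: pd.DataFrame) -> pd.DataFrame:
    """Per-electrode coherence: mean of pair values containing the electrode."""
    wc = table[table["measure"] == "wc"]
    if wc.empty:
        return wc.copy()
    expanded = []
    for _, row in wc.iterrows():
        for electrode in row["electrode"].split("-"):
            rec = row.copy()
            rec["electrode"] = electrode
            expanded.append(rec)
    long = pd.DataFrame(expanded)
    keys = ["subject_id", "group", "electrode", "band", "measure", "params"]
    return long.groupby(keys, as_index=False)["value"].mean()
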