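"""Group-discrimination screening: ANOVA p value and ROC AUC per feature.

Each measure is scored, per electrode (or electrode pair) and band, by
how well it separates two subject groups within the same eye condition
(A vs. C, B vs. D):

* one-way fixed-effects ANOVA p value (for two groups this equals a
  two-sided pooled t-test);
* area under the ROC curve, computed from the Mann-Whitney rank
  statistic with midrank tie handling and oriented to
  ``max(AUC, 1 - AUC)`` so that either direction of the effect counts
  as separation.

Measures with free parameters (quadratic entropy: tolerance r and
template length m; quantile graph: lag k at fixed Q) are scanned over
the study grids and the grid point with the lowest p value is selected,
ties broken toward the lexically smallest parameter tuple. p values are
reported raw, without multiple-testing correction, matching the
screening protocol they implement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bands import extract_band
from .core import GROUP_EYE_CONDITION
from .features.entropy import entropy_profile
from .features.graphs import build_quantile_graph, mean_jump_length
from .features.table import compute_series_measure, extract_features

__all__ = ["GroupComparison", "anova_p", "auc", "default_grid",
           "scan_parameters", "evaluate_measure", "electrode_summary",
           "validate_group_pair"]

#: Study parameter grids: entropy tolerance/template and QG lag.
QE_R_GRID = tuple(np.round(np.arange(1, 21) * 0.05, 2))   # 0.05 ... 1.00
QE_M_GRID = (1, 2)
QG_K_GRID = tuple(range(1, 26))                            # 1 ... 25
QG_Q = 20                                                  # 2 * 1024**(1/3) rounded


@dataclass
class GroupComparison:
    """Best screening result for one (measure, electrode, band, pair)."""

    group_pair: tuple[str, str]
    measure: str
    electrode: str
    band: str
    params: str
    p_value: float
    auc: float
    grid: pd.DataFrame = field(repr=False, default=None)


def validate_group_pair(pair: tuple[str, str]) -> tuple[str, str]:
    g1, g2 = pair
    if GROUP_EYE_CONDITION[g1] != GROUP_EYE_CONDITION[g2]:
        raise ValueError(
            f"groups {g1} and {g2} have different eye conditions; "
            "comparisons must not mix eye conditions"
        )
    if g1 == g2:
        raise ValueError("group pair must contain two distinct groups")
    return g1, g2


def anova_p(values_a, values_b) -> float:
    """One-way ANOVA p value between two groups of scalar features."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("zero variance within and between groups")
    f, p = stats.f_oneway(a, b)
    return float(p)


def auc(values_a, values_b, oriented: bool = True) -> float:
    """Rank-based AUC (ties count 1/2).

    With ``oriented=True`` (the screening convention) the value is
    folded to ``max(AUC, 1 - AUC)`` so either direction of the effect
    counts as separation; ``oriented=False`` returns the raw
    probability that a group-a value exceeds a group-b value, whose
    null expectation is exactly 0.5.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    u = stats.mannwhitneyu(a, b).statistic
    raw = float(u / (len(a) * len(b)))
    return max(raw, 1.0 - raw) if oriented else raw


def default_grid(measure: str) -> list[dict]:
    """Study parameter grid for a measure (single empty point if none)."""
    if measure == "qe":
        return [{"m": m, "r": float(r)}
                for m, r in itertools.product(QE_M_GRID, QE_R_GRID)]
    if measure == "qg":
        return [{"Q": QG_Q, "k": k} for k in QG_K_GRID]
    return [{}]


def _params_label(params: dict) -> str:
    return ",".join(f"{k}={v:g}" if isinstance(v, float) else f"{k}={v}"
                    for k, v in params.items())


def _screen(values_by_group: dict[str, np.ndarray],
            pair: tuple[str, str]) -> tuple[float, float]:
    return (anova_p(values_by_group[pair[0]], values_by_group[pair[1]]),
            auc(values_by_group[pair[0]], values_by_group[pair[1]]))


def scan_parameters(records, measure: str, band: str,
                    group_pair: tuple[str, str], electrode: str,
                    grid: list[dict] | None = None) -> GroupComparison:
    """Grid scan of one measure on one electrode; arg-min-p selection."""
    pair = validate_group_pair(group_pair)
    if grid is None:
        grid = default_grid(measure)
    if not grid:
        raise ValueError("empty parameter grid")
    selected = [rec for rec in records if rec.group in pair]
    series = {}
    # relative energy consumes the raw series (its band selects the
    # numerator coefficient set); all other measures see the band signal
    filter_input = measure != "we" and band != "original"
    for rec in selected:
        x = rec.channel(electrode)
        series[rec.subject_id] = (
            rec.group, extract_band(x, band, rec.fs) if filter_input else x)
    if measure == "qe":
        table = _scan_entropy(series, grid)
    elif measure == "qg":
        table = _scan_quantile(series, grid)
    else:
        table = _scan_generic(series, measure, band, grid)
    rows = []
    for label, values_by_group in table:
        if any(len(values_by_group.get(g, ())) < 2 for g in pair):
            continue  # undefined at this grid point for too many subjects
        p, a = _screen(values_by_group, pair)
        rows.append((label, p, a))
    if not rows:
        raise ValueError("no grid point produced defined values for both groups")
    grid_df = pd.DataFrame(rows, columns=["params", "p_value", "auc"])
    # lowest p; ties toward the lexically smallest parameter label
    best = grid_df.sort_values(["p_value", "params"], kind="stable").iloc[0]
    return GroupComparison(group_pair=pair, measure=measure,
                           electrode=electrode, band=band,
                           params=str(best["params"]),
                           p_value=float(best["p_value"]),
                           auc=float(best["auc"]), grid=grid_df)


def _scan_entropy(series, grid):
    by_m: dict[int, list[float]] = {}
    for point in grid:
        by_m.setdefault(point["m"], []).append(point["r"])
    out = {(_params_label({"m": m, "r": r})): {}
           for m in by_m for r in by_m[m]}
    for sid, (group, x) in series.items():
        for m, rs in by_m.items():
            profile = entropy_profile(x, m, np.asarray(rs))
            for r, value in profile.items():
                if value is None:
                    continue
                label = _params_label({"m": m, "r": r})
                out[label].setdefault(group, []).append(value)
    return [(label, {g: np.asarray(v) for g, v in vals.items()})
            for label, vals in out.items()]


def _scan_quantile(series, grid):
    out = []
    for point in grid:
        label = _params_label(point)
        values: dict[str, list[float]] = {}
        for sid, (group, x) in series.items():
            graph = build_quantile_graph(x, point["Q"], point["k"])
            values.setdefault(group, []).append(mean_jump_length(graph))
        out.append((label, {g: np.asarray(v) for g, v in values.items()}))
    return out


def _scan_generic(series, measure, band, grid):
    out = []
    for point in grid:
        label = _params_label(point)
        values: dict[str, list[float]] = {}
        for sid, (group, x) in series.items():
            value = compute_series_measure(x, measure, band=band, **point)
            values.setdefault(group, []).append(value)
        out.append((label, {g: np.asarray(v) for g, v in values.items()}))
    return out


def evaluate_measure(records, measure: str, band: str,
                     group_pair: tuple[str, str],
                     grid: list[dict] | None = None,
                     coherence_pairs=None) -> list[GroupComparison]:
    """Screen one measure on every electrode (or electrode pair).

    For the pairwise coherence, screening runs over electrode pairs;
    all other measures are screened per electrode with a parameter scan.
    """
    pair = validate_group_pair(group_pair)
    if measure == "wc":
        selected = [r for r in records if r.group in pair]
        table = extract_features(selected, measures=("wc",), bands=(band,),
                                 coherence_pairs=coherence_pairs)
        out = []
        for electrode, sub in table.groupby("electrode"):
            values = {g: sub.loc[sub["group"] == g, "value"].to_numpy()
                      for g in pair}
            if any(len(values[g]) < 2 for g in pair):
                continue
            p, a = _screen(values, pair)
            grid_df = pd.DataFrame([("", p, a)],
                                   columns=["params", "p_value", "auc"])
            out.append(GroupComparison(group_pair=pair, measure="wc",
                                       electrode=electrode, band=band,
                                       params="", p_value=p, auc=a,
                                       grid=grid_df))
        return out
    electrodes = records[0].channel_names
    return [scan_parameters(records, measure, band, pair, e, grid)
            for e in electrodes]


def electrode_summary(comparisons: list[GroupComparison],
                      electrodes: tuple[str, ...] | None = None,
                      ) -> tuple[pd.DataFrame, float]:
    """Tidy per-electrode table plus the mean p value over electrodes."""
    table = pd.DataFrame(
        [(c.electrode, c.band, c.measure, c.params, c.p_value, c.auc)
         for c in comparisons],
        columns=["electrode", "band", "measure", "params", "p_value", "auc"],
    )
    if electrodes is not None:
        missing = sorted(set(electrodes) - set(table["electrode"]))
        if missing:
            raise ValueError(f"missing electrodes: {', '.join(missing)}")
    return table, float(table["p_value"].mean())
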