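"""End-to-end orchestration: cohort -> features -> screening -> classification.

A run is a pure function of its configuration: the cohort is either
loaded from a directory or generated synthetically, every requested
(measure, band, group-pair) combination is screened per electrode with
its parameter grid, a best-per-measure table is assembled (measure,
electrode, band, groups, p, AUC), and the best setting of each measure
is handed to the SVM classifier for individual-level Acc/Sen/Spe.
Output tables are tab-delimited with provenance header comments (seed,
package version, configuration hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bands import BANDS_WITH_ORIGINAL, extract_band
from .classification import ClassificationReport, kfold_svm
from .core import AD_GROUPS
from .evaluation import (GroupComparison, electrode_summary, evaluate_measure,
                         validate_group_pair)
from .features.coherence import morlet_scales, wavelet_coherence
from .features.table import MEASURES, compute_series_measure
from .io import load_cohort
from .synthetic import CohortSpec, generate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    cohort_dir: str | None = None
    spec: CohortSpec | None = None
    measures: tuple[str, ...] = MEASURES
    bands: tuple[str, ...] = BANDS_WITH_ORIGINAL
    group_pairs: tuple[tuple[str, str], ...] = (("A", "C"), ("B", "D"))
    k_folds: int = 10
    seed: int = 0
    out_dir: str | None = None
    coherence_pairs: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if (self.cohort_dir is None) == (self.spec is None):
            raise ValueError("provide exactly one of cohort_dir or spec")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures {sorted(unknown)}")
        unknown_bands = set(self.bands) - set(BANDS_WITH_ORIGINAL)
        if unknown_bands:
            raise ValueError(f"unknown bands {sorted(unknown_bands)}")
        for pair in self.group_pairs:
            validate_group_pair(pair)

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: (v if not isinstance(v, CohortSpec) else vars(v))
                   for k, v in vars(self).items() if k != "out_dir"}
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha1(text.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Bundle of every table a run produces."""

    config: RunConfig
    comparisons: list[GroupComparison]
    summaries: dict[tuple[str, str, str, str], pd.DataFrame]
    mean_p: dict[tuple[str, str, str, str], float]
    best_table: pd.DataFrame
    classification_table: pd.DataFrame


def _parse_params(label: str) -> dict:
    out: dict = {}
    if not label:
        return out
    for item in label.split(","):
        key, _, value = item.partition("=")
        out[key] = int(value) if key in ("m", "Q", "k") else float(value)
    return out


def _feature_values(records, comparison: GroupComparison):
    """Per-subject feature values at a comparison's chosen setting."""
    pair = comparison.group_pair
    selected = [r for r in records if r.group in pair]
    params = _parse_params(comparison.params)
    values, labels = [], []
    for rec in selected:
        if comparison.measure == "wc":
            ch_a, ch_b = comparison.electrode.split("-")
            scales = morlet_scales(rec.fs)
            xa, xb = rec.channel(ch_a), rec.channel(ch_b)
            if comparison.band != "original":
                xa = extract_band(xa, comparison.band, rec.fs)
                xb = extract_band(xb, comparison.band, rec.fs)
            _, value = wavelet_coherence(xa, xb, rec.fs, scales=scales)
        else:
            x = rec.channel(comparison.electrode)
            if comparison.band != "original" and comparison.measure != "we":
                x = extract_band(x, comparison.band, rec.fs)
            value = compute_series_measure(x, comparison.measure,
                                           band=comparison.band, **params)
        values.append(value)
        labels.append(rec.group in AD_GROUPS)
    return np.asarray(values), np.asarray(labels)


def run_pipeline(config: RunConfig) -> PipelineResult:
    if config.cohort_dir is not None:
        _, records = load_cohort(config.cohort_dir)
    else:
        records = generate_cohort(config.spec)
    if not records:
        raise ValueError("pipeline: empty cohort")
    coh_pairs = (list(config.coherence_pairs)
                 if config.coherence_pairs is not None else None)

    comparisons: list[GroupComparison] = []
    summaries: dict = {}
    mean_p: dict = {}
    for pair in config.group_pairs:
        for measure in config.measures:
            bands = config.bands
            if measure == "we":
                # relative energy of an unfiltered signal is identically 1
                bands = tuple(b for b in bands if b != "original")
            for band in bands:
                try:
                    comps = evaluate_measure(records, measure, band, pair,
                                             coherence_pairs=coh_pairs)
                except ValueError as exc:
                    raise ValueError(
                        f"evaluation failed at measure={measure}, band={band}, "
                        f"pair={pair}: {exc}") from exc
                comparisons.extend(comps)
                table, avg = electrode_summary(comps)
                key = (measure, band, *pair)
                summaries[key] = table
                mean_p[key] = avg

    best_rows = []
    class_rows = []
    n_ad = sum(1 for r in records if r.group in AD_GROUPS)
    n_healthy = len(records) - n_ad
    for measure in config.measures:
        cands = [c for c in comparisons if c.measure == measure]
        if not cands:
            continue
        best = min(cands, key=lambda c: (c.p_value, c.band, c.electrode))
        best_rows.append((measure, best.electrode, best.band,
                          f"{best.group_pair[0]} vs {best.group_pair[1]}",
                          best.params, best.p_value, best.auc))
        values, labels = _feature_values(records, best)
        k = min(config.k_folds, int(labels.sum()), int((~labels).sum()))
        k = max(k, 2)
        report = kfold_svm(values, labels, k=k, seed=config.seed)
        class_rows.append((measure, best.electrode, best.band,
                           f"{best.group_pair[0]} vs {best.group_pair[1]}",
                           report.k, report.accuracy, report.sensitivity,
                           report.specificity))
    best_table = pd.DataFrame(
        best_rows, columns=["measure", "electrode", "band", "groups",
                            "params", "p_value", "auc"])
    classification_table = pd.DataFrame(
        class_rows, columns=["measure", "electrode", "band", "groups",
                             "k", "accuracy", "sensitivity", "specificity"])
    result = PipelineResult(config=config, comparisons=comparisons,
                            summaries=summaries, mean_p=mean_p,
                            best_table=best_table,
                            classification_table=classification_table)
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
    return result


def _provenance(config: RunConfig) -> str:
    return (f"# eegmarkers {__version__}\n"
            f"# seed={config.seed}\n"
            f"# config={config.digest()}\n"
            "# p values are raw (no multiple-testing correction)\n")


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config = result.config
    _write_table(result.best_table, out_dir / "best_per_measure.tsv", config)
    _write_table(result.classification_table,
                 out_dir / "classification.tsv", config)
    for (measure, band, g1, g2), table in result.summaries.items():
        name = f"summary_{measure}_{band}_{g1}{g2}.tsv"
        annotated = table.copy()
        annotated["mean_p_over_electrodes"] = result.mean_p[(measure, band, g1, g2)]
        _write_table(annotated, out_dir / name, config)
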