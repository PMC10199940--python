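"""Individual-level SVM classification with stratified K-fold validation.

A support vector machine (RBF kernel, C = 1) is trained on a single
selected feature to separate probable-AD subjects from healthy elderly
controls. Folds are stratified so the small control group is present in
every fold, features are standardised with statistics fit on the
training folds only, and the out-of-fold predictions are pooled into one
confusion matrix. AD is the positive class:

    Acc = (TP + TN) / total,  Sen = TP / (TP + FN),  Spe = TN / (TN + FP),

all reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["ClassificationReport", "kfold_svm"]


@dataclass
class ClassificationReport:
    """Pooled cross-validated confusion counts and summary rates (%)."""

    k: int
    seed: int
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    tn: int
    fp: int
    fn: int
    fold_confusions: list[tuple[int, int, int, int]] = field(repr=False,
                                                             default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def kfold_svm(values, labels, k: int = 10, seed: int = 0) -> ClassificationReport:
    """Cross-validated SVM on per-subject feature values.

    Parameters
    ----------
    values : array-like, shape (n,) or (n, d)
        Feature value(s) per subject.
    labels : array-like of bool, shape (n,)
        True for probable-AD subjects (the positive class).
    k : int
        Number of stratified folds; clipped to the minority class size
        cannot be required, but every fold must receive >= 1 subject.
    seed : int
        Shuffling seed; the report is a deterministic function of
        (values, labels, k, seed).
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=bool)
    if len(X) != len(y):
        raise ValueError("values and labels length mismatch")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature values must be finite")
    if y.all() or not y.any():
        raise ValueError("labels contain a single class")
    if k < 2:
        raise ValueError("K must be >= 2")
    if k > len(y):
        raise ValueError("K exceeds the number of subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tp = tn = fp = fn = 0
    folds = []
    for train_idx, test_idx in skf.split(X, y):
        model = make_pipeline(StandardScaler(), SVC(C=1.0, kernel="rbf"))
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        truth = y[test_idx]
        f_tp = int(np.sum(pred & truth))
        f_tn = int(np.sum(~pred & ~truth))
        f_fp = int(np.sum(pred & ~truth))
        f_fn = int(np.sum(~pred & truth))
        folds.append((f_tp, f_tn, f_fp, f_fn))
        tp, tn, fp, fn = tp + f_tp, tn + f_tn, fp + f_fp, fn + f_fn
    total = tp + tn + fp + fn
    return ClassificationReport(
        k=k, seed=seed,
        accuracy=100.0 * (tp + tn) / total,
        sensitivity=100.0 * tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=100.0 * tn / (tn + fp) if (tn + fp) else float("nan"),
        tp=tp, tn=tn, fp=fp, fn=fn, fold_confusions=folds,
    )
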