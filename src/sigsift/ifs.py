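"""Incremental feature selection with SVM leave-one-out cross-validation.

Given a ranked gene list, how many of the top genes make the best
classifier?  IFS answers by brute force: evaluate the nested prefixes
top-1, top-2, ... by leave-one-out cross-validated accuracy of a linear
support-vector machine, and pick the prefix at the accuracy peak (smallest
k on ties).  Each LOOCV fold standardizes genes on its training samples
only, so the held-out sample never leaks into the scaling.  The selected
prefix is the expression signature; its quality is summarized by a
predicted-vs-actual confusion matrix with per-class accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .matrix import validate_matrix, validate_labels
from .mcfs import RankedFeatureList

__all__ = [
    "ClassifierParams",
    "ConfusionMatrix",
    "IFSCurve",
    "loocv_evaluate",
    "default_ifs_grid",
    "ifs_curve",
    "select_signature",
    "confusion_stats",
]


@dataclass(frozen=True)
class ClassifierParams:
    kernel: str = "linear"
    regularization: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")

    def make_estimator(self):
        scaler = StandardScaler()
        if self.kernel == "linear":
            # one-vs-rest linear SVM; robust when genes far outnumber samples
            clf = LinearSVC(C=self.regularization, random_state=self.seed)
        else:
            clf = SVC(C=self.regularization, kernel=self.kernel, random_state=self.seed)
        return make_pipeline(scaler, clf)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Predicted (rows) vs actual (columns) counts for K classes."""

    counts: pd.DataFrame

    @property
    def classes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts.to_numpy()) / self.counts.to_numpy().sum())

    @property
    def per_class_accuracy(self) -> pd.Series:
        diag = pd.Series(np.diag(self.counts.to_numpy()), index=self.counts.columns)
        sizes = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = diag / sizes
        return acc

    def to_table(self) -> pd.DataFrame:
        """Display table: counts plus sample-size and accuracy rows (3 decimals)."""
        table = self.counts.copy().astype(object)
        table.index = [f"Predicted{c}" for c in table.index]
        table.columns = [f"Actual{c}" for c in table.columns]
        table.loc["Sample size"] = self.counts.sum(axis=0).to_numpy()
        table.loc["Accuracy"] = [f"{a:.3f}" for a in self.per_class_accuracy]
        return table


@dataclass(frozen=True)
class IFSCurve:
    """(k, LOOCV accuracy) pairs with strictly increasing k."""

    points: tuple[tuple[int, float], ...]

    def __post_init__(self):
        ks = [k for k, _ in self.points]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("curve k values must be strictly increasing")
        if any(not 0 <= a <= 1 for _, a in self.points):
            raise ValueError("accuracies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["k", "accuracy"])


def loocv_evaluate(
    m: pd.DataFrame, labels: pd.Series, cp: ClassifierParams = ClassifierParams()
) -> tuple[float, ConfusionMatrix]:
    """Leave-one-out accuracy and confusion matrix on a gene subset.

    Each sample is predicted by a classifier trained on all other samples;
    standardization parameters are fit per fold.  Deterministic given inputs.
    """
    m = validate_matrix(m)
    labels = validate_labels(labels, m)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 classes")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(
            f"classes with a single sample cannot be cross-validated leave-one-out: {bad}"
        )
    X = m.to_numpy().T
    y = labels.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LinearSVC convergence chatter on tiny folds
        pred = cross_val_predict(cp.make_estimator(), X, y, cv=LeaveOneOut(), n_jobs=1)
    classes = sorted(counts.index)
    grid = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for a, p in zip(y, pred):
        grid.loc[p, a] += 1
    cm = ConfusionMatrix(counts=grid)
    accuracy = float((pred == y).mean())
    return accuracy, cm


def default_ifs_grid(max_k: int, dense_until: int = 200, stride: int = 5) -> list[int]:
    """Every k up to ``dense_until``, then every ``stride``-th, always ending at max_k."""
    ks = list(range(1, min(max_k, dense_until) + 1))
    ks += list(range(dense_until + stride, max_k + 1, stride))
    if ks[-1] != max_k:
        ks.append(max_k)
    return ks


def ifs_curve(
    ranked: RankedFeatureList,
    m: pd.DataFrame,
    labels: pd.Series,
    cp: ClassifierParams = ClassifierParams(),
    max_k: int | None = None,
    step: int = 1,
    ks: list[int] | None = None,
) -> IFSCurve:
    """Evaluate nested top-k prefixes of the ranking for k = step, 2*step, ..., max_k.

    An explicit increasing grid ``ks`` overrides the regular (step, max_k)
    grid; :func:`default_ifs_grid` gives the dense-then-strided schedule used
    by the end-to-end pipeline.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    max_k = (ranked.N if max_k is None else max_k) if ks is None else max(ks)
    if not 1 <= max_k <= ranked.N:
        raise ValueError(f"max_k must lie in [1, {ranked.N}]")
    if ks is None:
        ks = list(range(step, max_k + 1, step))
        if not ks or ks[-1] != max_k:
            ks.append(max_k)
    points = []
    for k in ks:
        acc, _ = loocv_evaluate(m.loc[ranked.top(k)], labels, cp)
        points.append((k, acc))
    return IFSCurve(points=tuple(points))


def select_signature(curve: IFSCurve, ranked: RankedFeatureList) -> tuple[int, list[str]]:
    """Smallest k attaining the curve's maximum accuracy, and its genes."""
    if not curve.points:
        raise ValueError("empty IFS curve")
    best = max(a for _, a in curve.points)
    k_star = min(k for k, a in curve.points if a == best)
    return k_star, ranked.top(k_star)


def confusion_stats(cm: ConfusionMatrix) -> tuple[pd.Series, float]:
    """Per-class accuracies (diag / column sum) and overall accuracy (trace / total).

    A class absent from the actual samples (zero column sum) gets NaN and a
    warning; callers display at 3 decimals.
    """
    per_class = cm.per_class_accuracy
    if per_class.isna().any():
        empty = per_class.index[per_class.isna()].tolist()
        warnings.warn(f"classes with no actual samples; accuracy undefined: {empty}")
    return per_class, cm.overall_accuracy
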