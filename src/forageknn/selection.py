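"""Nested stratified cross-validation and evaluation statistics.

The hyperparameters of the fuzzy k-NN classifier — neighborhood size ``k``
and fuzzy strength ``m`` — are tuned by the bacterial foraging optimizer on
an inner stratified cross-validation loop, while an outer stratified loop
measures generalization.  The outer held-out fold never reaches the inner
objective, and the [0, 1] feature scaling is fitted on each outer training
split only, so the reported accuracy, AUC, sensitivity and specificity are
leakage-free.

The optimizer works on a continuous 2-D box; :func:`decode_position` maps a
raw position to a usable pair (round-and-clamp for the integer ``k``, clamp
for ``m``).  The inner objective is the mean misclassification rate across
the inner folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cbfo, fknn
from .datasets import scale_minmax
from .exceptions import ContractError, StratificationError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "CvRecord",
    "NestedCvResult",
    "stratified_folds",
    "decode_position",
    "inner_fitness",
    "tune_fold",
    "nested_cv",
    "compute_metrics",
    "compute_auc",
    "rank_sum_compare",
    "confusion_counts",
]

M_EPSILON = 0.01  # lower clamp margin keeping m strictly above 1


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class CvRecord:
    """Per-outer-fold evaluation and the hyperparameters it used."""

    fold: int
    acc: float  # percent
    auc: float  # 0..1
    sensitivity: float  # percent
    specificity: float  # percent
    k: int
    m: float
    train_indices: np.ndarray = field(repr=False, default=None)
    test_indices: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class NestedCvResult:
    """Outer-loop records plus their arithmetic mean row."""

    records: list[CvRecord]

    @property
    def mean_acc(self) -> float:
        return float(np.mean([r.acc for r in self.records]))

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.auc for r in self.records]))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([r.sensitivity for r in self.records]))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean([r.specificity for r in self.records]))

    def to_dataframe(self, include_mean: bool = True) -> pd.DataFrame:
        rows = [
            {"fold": r.fold, "ACC": r.acc, "AUC": r.auc, "Sen": r.sensitivity,
             "Spec": r.specificity, "k": r.k, "m": r.m}
            for r in self.records
        ]
        df = pd.DataFrame(rows)
        if include_mean:
            mean = {
                "fold": "Mean",
                "ACC": self.mean_acc,
                "AUC": self.mean_auc,
                "Sen": self.mean_sensitivity,
                "Spec": self.mean_specificity,
                "k": float(np.mean([r.k for r in self.records])),
                "m": float(np.mean([r.m for r in self.records])),
            }
            df = pd.concat([df, pd.DataFrame([mean])], ignore_index=True)
        return df


def stratified_folds(labels, n_folds: int, seed=None) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Shuffles each class separately and deals its samples round-robin, so
    per-class counts differ by at most one across folds.  Raises if any
    class has fewer samples than folds (some fold would miss the class).
    """
    y = np.asarray(labels)
    if n_folds < 2:
        raise ContractError("need at least 2 folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if len(idx) < n_folds:
            raise StratificationError(
                f"class {cls!r} has {len(idx)} samples < {n_folds} folds"
            )
        idx = idx[rng.permutation(len(idx))]
        assignment[idx] = (np.arange(len(idx)) + offset) % n_folds
        # stagger the dealing start so small classes spread over all folds
        offset += len(idx)
    return assignment


def decode_position(raw_point, k_max: int, m_range=(1.0 + M_EPSILON, 10.0)
                    ) -> tuple[int, float]:
    """Map a raw 2-D optimizer position to a valid ``(k, m)`` pair."""
    x = np.asarray(raw_point, dtype=float)
    k = int(np.clip(np.rint(x[0]), 1, k_max))
    lo, hi = m_range
    lo = max(lo, 1.0 + M_EPSILON)
    m = float(np.clip(x[1], lo, hi))
    return k, m


def inner_fitness(features, labels, k: int, m: float, inner_folds: int = 5,
                  seed=None, folds: np.ndarray | None = None) -> float:
    """Mean misclassification rate of FKNN(k, m) over stratified inner folds.

    Equals ``1 - mean(inner accuracy) / 100``; lies in [0, 1].  ``folds``
    may carry a precomputed assignment (as produced by
    :func:`stratified_folds`) so that every hyperparameter pair is judged
    on identical splits.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if folds is None:
        folds = stratified_folds(y, inner_folds, seed)
    errors = []
    for f in range(int(folds.max()) + 1):
        test = folds == f
        train = ~test
        k_eff = min(int(k), int(train.sum()) - 1)
        model = fknn.fit(X[train], y[train], k=k_eff, m=m)
        pred = fknn.classify(model, X[test])
        errors.append(float(np.mean(pred != y[test])))
    return float(np.mean(errors))


def tune_fold(features, labels, config: cbfo.CbfoConfig | None = None,
              k_max: int | None = None, m_range=(1.0 + M_EPSILON, 10.0),
              seed=None, inner_folds: int = 5) -> tuple[int, float, float]:
    """Select ``(k, m)`` by bacterial foraging over the inner-CV error.

    Returns ``(k, m, best_fitness)``.  The inner fold assignment is fixed
    once (from ``seed``) and reused for every candidate, and evaluated
    pairs are cached, so the search is deterministic for a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if config is None:
        config = cbfo.CbfoConfig.tuning_default()
    n = len(y)
    if k_max is None:
        k_max = min(50, n - 1)
    k_max = int(min(k_max, n - 1))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = stratified_folds(y, inner_folds, rng)

    cache: dict[tuple[int, float], float] = {}

    def objective(points: np.ndarray) -> np.ndarray:
        out = np.empty(len(points))
        for i, pt in enumerate(points):
            kk, mm = decode_position(pt, k_max, m_range)
            key = (kk, round(mm, 12))
            if key not in cache:
                cache[key] = inner_fitness(X, y, kk, mm, folds=folds)
            out[i] = cache[key]
        return out

    bounds = np.array([[1.0, float(k_max)], [m_range[0], m_range[1]]])
    result = cbfo.optimize(objective, bounds, config, seed=rng)
    k, m = decode_position(result.best_position, k_max, m_range)
    return k, m, float(result.best_cost)


def confusion_counts(y_true, y_pred, positive_label=1) -> ConfusionCounts:
    """Binary confusion counts with ``positive_label`` as the positive class."""
    t = np.asarray(y_true) == positive_label
    p = np.asarray(y_pred) == positive_label
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fn=int((t & ~p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
    )


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Accuracy, sensitivity and specificity in percent.

    ``ACC = (TP + TN) / total``, ``Sens = TP / (TP + FN)``,
    ``Spec = TN / (FP + TN)``, each times 100.
    """
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise UndefinedMetricError("a class margin is empty")
    acc = (counts.tp + counts.tn) / counts.total * 100.0
    sens = counts.tp / (counts.tp + counts.fn) * 100.0
    spec = counts.tn / (counts.fp + counts.tn) * 100.0
    return acc, sens, spec


def compute_auc(scores, labels, positive_label=1) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    Ties receive midranks; the result is the probability that a random
    positive scores above a random negative (ties counting one half).
    """
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == positive_label
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC requires both classes")
    ranks = stats.rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def rank_sum_compare(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two result samples.

    Uses exact enumeration for small tie-free samples (combined n <= 12)
    and the normal approximation with tie correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ContractError("each sample needs at least 3 observations")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def nested_cv(features, labels, config: cbfo.CbfoConfig | None = None,
              outer_folds: int = 10, inner_folds: int = 5,
              k_max: int | None = None, m_range=(1.0 + M_EPSILON, 10.0),
              seed=None, positive_label=1) -> NestedCvResult:
    """Nested stratified cross-validation of the tuned fuzzy k-NN.

    For each outer fold the remaining folds are min-max scaled (fit on
    train, applied to the held-out fold), ``(k, m)`` is tuned by
    :func:`tune_fold` on the training part alone, a fuzzy k-NN with the
    selected pair is fitted on the full training part and evaluated on the
    held-out fold.  The positive-class fuzzy membership is used as the AUC
    score.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ContractError("nested_cv expects a two-class problem")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    split_seed, *fold_seeds = ss.spawn(outer_folds + 1)
    folds = stratified_folds(y, outer_folds, np.random.default_rng(split_seed))

    records = []
    for f in range(outer_folds):
        test = folds == f
        train = ~test
        X_tr, X_te, _ = scale_minmax(X[train], X[test])
        y_tr, y_te = y[train], y[test]
        k, m, _fit_err = tune_fold(
            X_tr, y_tr, config=config, k_max=k_max, m_range=m_range,
            seed=np.random.default_rng(fold_seeds[f]), inner_folds=inner_folds,
        )
        model = fknn.fit(X_tr, y_tr, k=min(k, len(y_tr) - 1), m=m)
        memberships = np.atleast_2d(fknn.predict_memberships(model, X_te))
        pos_col = int(np.nonzero(model.classes_ == positive_label)[0][0])
        scores = memberships[:, pos_col]
        pred = model.classes_[memberships.argmax(axis=1)]
        acc, sens, spec = compute_metrics(confusion_counts(y_te, pred, positive_label))
        auc = compute_auc(scores, y_te, positive_label)
        records.append(
            CvRecord(fold=f + 1, acc=acc, auc=auc, sensitivity=sens,
                     specificity=spec, k=k, m=m,
                     train_indices=np.nonzero(train)[0],
                     test_indices=np.nonzero(test)[0])
        )
    return NestedCvResult(records=records)
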