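"""Imbalance-aware metrics, ROC/AUC, scatter diagnostics and the
cross-validated experiment harness.

Feature selection and resampling are fit/applied on the training folds
only; test folds keep their original, imbalanced composition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from toxbalance import ensemble as ens
from toxbalance import roughset, sampling
from toxbalance.data import DescriptorTable, make_folds


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn,
                               self.tn + other.tn, self.fp + other.fp)

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    fpr: float
    gm: float

    def as_dict(self) -> dict[str, float]:
        return dict(accuracy=self.accuracy, sensitivity=self.sensitivity,
                    specificity=self.specificity, fpr=self.fpr, gm=self.gm)


@dataclass
class RocCurve:
    """(FPR, TPR) points sorted from the strictest threshold to the laxest,
    plus the trapezoid area."""

    points: list[tuple[float, float]]
    auc: float


@dataclass(frozen=True)
class ScatterDiagnostic:
    """Class-scatter decomposition.

    The two scatter fields are sums over samples and add up to the total
    scatter about the grand mean; the ``*_per_sample`` views divide by the
    pool size, which is the right scale for comparing pools of different
    sizes (resampling changes the row count).
    """

    between_class_variance: float
    within_class_variance: float
    n_samples: int

    @property
    def total(self) -> float:
        return self.between_class_variance + self.within_class_variance

    @property
    def between_per_sample(self) -> float:
        return self.between_class_variance / self.n_samples

    @property
    def within_per_sample(self) -> float:
        return self.within_class_variance / self.n_samples


def confusion(labels_true: np.ndarray, labels_pred: np.ndarray) -> ConfusionCounts:
    """Exact TP/FN/TN/FP counts; positive class is label 1."""
    y = np.asarray(labels_true, dtype=np.int64)
    p = np.asarray(labels_pred, dtype=np.int64)
    if y.shape != p.shape:
        raise MetricError("label vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
    )


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity (TPR), specificity (TNR), FPR, and the
    geometric mean sqrt(sensitivity * specificity)."""
    if counts.n_positive == 0 or counts.n_negative == 0:
        raise MetricError("metrics undefined when a class is empty")
    total = counts.n_positive + counts.n_negative
    sens = counts.tp / counts.n_positive
    spec = counts.tn / counts.n_negative
    return MetricSet(
        accuracy=(counts.tp + counts.tn) / total,
        sensitivity=sens,
        specificity=spec,
        fpr=counts.fp / counts.n_negative,
        gm=math.sqrt(sens * spec),
    )


def roc_auc(labels_true: np.ndarray, scores: np.ndarray) -> RocCurve:
    """ROC by descending-threshold sweep over the unique scores; tied scores
    step simultaneously; area by the trapezoid rule."""
    y = np.asarray(labels_true, dtype=np.int64)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise MetricError("labels and scores differ in length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise MetricError("ROC undefined with a single class")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score run
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=list(zip(fpr.tolist(), tpr.tolist())), auc=auc)


def scatter_diagnostic(pool: sampling.SamplePool) -> ScatterDiagnostic:
    """Between-class scatter sum_c n_c ||mu_c - mu||^2 and within-class
    scatter sum_c sum_x ||x - mu_c||^2; they add to the total scatter about
    the grand mean."""
    pool.require_both_classes()
    x = pool.features
    grand = x.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in (0, 1):
        xc = x[pool.labels == c]
        mu = xc.mean(axis=0)
        between += xc.shape[0] * float(np.sum((mu - grand) ** 2))
        within += float(np.sum((xc - mu) ** 2))
    return ScatterDiagnostic(between_class_variance=between,
                             within_class_variance=within,
                             n_samples=x.shape[0])


# ---------------------------------------------------------------------------
# cross-validated harness

@dataclass
class FoldOutcome:
    fold: int
    counts: ConfusionCounts
    metric_set: MetricSet
    roc: RocCurve
    selected_features: list[str]


@dataclass
class EvaluationReport:
    folds: list[FoldOutcome] = field(default_factory=list)
    pooled: MetricSet | None = None          # micro: summed confusion counts
    macro: dict[str, float] = field(default_factory=dict)  # mean of per-fold metrics
    pooled_counts: ConfusionCounts | None = None
    pooled_auc: float = 0.0
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "config": self.config,
            "pooled": self.pooled.as_dict() if self.pooled else None,
            "pooled_auc": self.pooled_auc,
            "macro": self.macro,
            "folds": [
                {
                    "fold": f.fold,
                    "counts": {"tp": f.counts.tp, "fn": f.counts.fn,
                               "tn": f.counts.tn, "fp": f.counts.fp},
                    "metrics": f.metric_set.as_dict(),
                    "auc": f.roc.auc,
                    "selected_features": f.selected_features,
                }
                for f in self.folds
            ],
        }, indent=2)


def _select_features(train_values: np.ndarray, train_labels: np.ndarray,
                     feature_names: list[str], method: str,
                     n_bins: int) -> list[int]:
    if method == "none":
        return list(range(train_values.shape[1]))
    table, _ = roughset.discretize(train_values, n_bins=n_bins,
                                   attribute_names=feature_names,
                                   decision=train_labels)
    result = roughset.REDUCT_METHODS[method](table)
    return sorted(result.selected) or list(range(train_values.shape[1]))


def cross_validate(table: DescriptorTable, endpoint: str,
                   fs_method: str = "none", sampling_method: str = "none",
                   T: int = 3, learner_spec: ens.LearnerSpec | None = None,
                   k_folds: int = 5, seed: int = 0, n_bins: int = 3,
                   k_init: int = 15, k_neighbors: int = 5) -> EvaluationReport:
    """Stratified k-fold evaluation of the full pipeline.

    Per fold: discretize + select features on the training part, rebalance
    the training part, train the bagging ensemble, score the untouched test
    part.  Pooled (micro) metrics come from summed fold confusions; macro
    metrics average the per-fold values.
    """
    if endpoint not in table.labels:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if fs_method not in ("none", *roughset.REDUCT_METHODS):
        raise ValueError(f"unknown feature-selection method {fs_method!r}")
    if sampling_method not in ("none", *sampling.SAMPLING_METHODS):
        raise ValueError(f"unknown sampling method {sampling_method!r}")

    labels = table.labels[endpoint]
    plan = make_folds(labels, k=k_folds, stratified=True, seed=seed)
    rng = np.random.default_rng(seed)

    report = EvaluationReport(config={
        "endpoint": endpoint, "fs_method": fs_method,
        "sampling_method": sampling_method, "T": T, "k_folds": k_folds,
        "seed": seed, "n_bins": n_bins, "k_init": k_init,
        "k_neighbors": k_neighbors,
    })

    all_scores = np.zeros(table.n_samples)
    all_pred = np.zeros(table.n_samples, dtype=np.int64)
    total = ConfusionCounts(0, 0, 0, 0)
    for fold in range(k_folds):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        fold_seed = int(rng.integers(0, 2**31))

        cols = _select_features(table.values[tr], labels[tr],
                                table.feature_names, fs_method, n_bins)
        x_tr, x_te = table.values[tr][:, cols], table.values[te][:, cols]

        pool = sampling.SamplePool(features=x_tr, labels=labels[tr])
        if sampling_method != "none":
            pool = sampling.SAMPLING_METHODS[sampling_method](
                pool, seed=fold_seed, k_init=k_init, k_neighbors=k_neighbors)

        model = ens.train_bagging(pool, T=T, learner_spec=learner_spec,
                                  seed=fold_seed)
        preds = ens.predict(model, x_te)
        pred_labels = np.array([p.label for p in preds], dtype=np.int64)
        scores = np.array([p.score for p in preds])
        all_scores[te] = scores
        all_pred[te] = pred_labels

        counts = confusion(labels[te], pred_labels)
        total = total + counts
        report.folds.append(FoldOutcome(
            fold=fold, counts=counts, metric_set=metrics(counts),
            roc=roc_auc(labels[te], scores),
            selected_features=[table.feature_names[c] for c in cols],
        ))

    report.pooled_counts = total
    report.pooled = metrics(total)
    keys = ("accuracy", "sensitivity", "specificity", "fpr", "gm")
    report.macro = {k: float(np.mean([f.metric_set.as_dict()[k] for f in report.folds]))
                    for k in keys}
    report.pooled_auc = roc_auc(labels, all_scores).auc
    return report
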