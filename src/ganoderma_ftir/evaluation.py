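"""Confusion matrices, the pooled one-vs-rest metric battery, and run summaries.

Conventions follow the study design this package reproduces:

* confusion matrices are oriented rows = predicted, columns = true;
* accuracy, sensitivity and specificity are micro-averages computed from
  one-vs-rest TP/TN/FP/FN counts pooled over classes (for K balanced-or-not
  classes these satisfy the exact identities ``acc = 1 - 2e/K`` and
  ``spec = 1 - e/(K-1)`` with ``e = 1 - sens``, all as proportions);
* precision, recall and F1 are macro-averages of per-class values;
* run summaries report mean, population standard deviation (divisor n) and
  the coefficient of variation ``100 * sd / mean``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectraSet

__all__ = [
    "ConfusionMatrix",
    "OvrCounts",
    "RunMetrics",
    "RunSummary",
    "confusion_matrix",
    "ovr_counts",
    "core_metrics",
    "macro_prf",
    "run_metrics",
    "random_segregation_test",
    "summarize_runs",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count matrix; ``counts[i, j]`` = predicted class i, true class j."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        k = len(self.class_order)
        if counts.shape != (k, k):
            raise ValueError("counts must be K x K for K classes")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def transposed(self) -> "ConfusionMatrix":
        """Rows = true, columns = predicted (interoperability orientation)."""
        return ConfusionMatrix(self.counts.T.copy(), self.class_order)


@dataclass(frozen=True)
class OvrCounts:
    """One-vs-rest true/false positive/negative counts (per class or pooled)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class RunMetrics:
    """Metric battery of a single evaluation run.

    accuracy/sensitivity/specificity are pooled (micro) percentages;
    precision/recall/f1 are macro proportions.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass(frozen=True)
class RunSummary:
    """Per-run metrics plus mean / population sd / CV per metric."""

    per_run: tuple[RunMetrics, ...]
    mean: dict[str, float]
    sd: dict[str, float]
    cv: dict[str, float]


def confusion_matrix(
    true_labels, predicted_labels, class_order: tuple[str, ...] | list[str]
) -> ConfusionMatrix:
    """Count matrix with rows = predicted, columns = true."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class_order: {t!r}/{p!r}")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts, tuple(class_order))


def ovr_counts(cm: ConfusionMatrix) -> tuple[dict[str, OvrCounts], OvrCounts]:
    """Per-class and pooled one-vs-rest counts.

    For class c (row/column index i): tp = counts[i, i], fp = rest of row i
    (predicted c but not c), fn = rest of column i, tn = everything else.
    Pooled counts are the sums over classes; pooled fp always equals pooled fn
    because every misclassification is one FP and one FN.
    """
    if len(cm.class_order) < 2:
        raise ValueError("need at least two classes")
    n = cm.n_samples
    per_class: dict[str, OvrCounts] = {}
    for i, cls in enumerate(cm.class_order):
        tp = int(cm.counts[i, i])
        fp = int(cm.counts[i, :].sum()) - tp
        fn = int(cm.counts[:, i].sum()) - tp
        tn = n - tp - fp - fn
        per_class[cls] = OvrCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    pooled = OvrCounts(
        tp=sum(c.tp for c in per_class.values()),
        tn=sum(c.tn for c in per_class.values()),
        fp=sum(c.fp for c in per_class.values()),
        fn=sum(c.fn for c in per_class.values()),
    )
    return per_class, pooled


def core_metrics(pooled: OvrCounts) -> tuple[float, float, float]:
    """Accuracy, sensitivity, specificity in percent from pooled OVR counts.

    accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), each * 100.
    """
    if pooled.total == 0 or (pooled.tp + pooled.fn) == 0 or (pooled.tn + pooled.fp) == 0:
        raise ZeroDivisionError("undefined metric: zero denominator in pooled counts")
    accuracy = 100.0 * (pooled.tp + pooled.tn) / pooled.total
    sensitivity = 100.0 * pooled.tp / (pooled.tp + pooled.fn)
    specificity = 100.0 * pooled.tn / (pooled.tn + pooled.fp)
    return accuracy, sensitivity, specificity


def macro_prf(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Macro precision, recall and F1 (proportions).

    Per class: precision = tp/(tp+fp), recall = tp/(tp+fn),
    f1 = 2pr/(p+r); classes with an empty denominator contribute 0 with a
    warning.  Macro value = unweighted mean over classes.
    """
    per_class, _ = ovr_counts(cm)
    precisions, recalls, f1s = [], [], []
    for cls, c in per_class.items():
        if c.tp + c.fp == 0:
            warnings.warn(f"class {cls!r} never predicted; precision set to 0", stacklevel=2)
            p = 0.0
        else:
            p = c.tp / (c.tp + c.fp)
        if c.tp + c.fn == 0:
            warnings.warn(f"class {cls!r} absent from truth; recall set to 0", stacklevel=2)
            r = 0.0
        else:
            r = c.tp / (c.tp + c.fn)
        f = 0.0 if (p + r) == 0 else 2 * p * r / (p + r)
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    return float(np.mean(precisions)), float(np.mean(recalls)), float(np.mean(f1s))


def run_metrics(cm: ConfusionMatrix) -> RunMetrics:
    """Full battery for one confusion matrix."""
    _, pooled = ovr_counts(cm)
    accuracy, sensitivity, specificity = core_metrics(pooled)
    precision, recall, f1 = macro_prf(cm)
    return RunMetrics(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        recall=recall,
        f1=f1,
    )


def summarize_runs(per_run: list[RunMetrics] | tuple[RunMetrics, ...]) -> RunSummary:
    """Mean, population sd (divisor n) and CV = 100*sd/mean per metric."""
    if len(per_run) < 2:
        raise ValueError("need at least two runs to summarize")
    names = ("accuracy", "sensitivity", "specificity", "precision", "recall", "f1")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    cv: dict[str, float] = {}
    for name in names:
        values = np.array([getattr(r, name) for r in per_run], dtype=float)
        mean[name] = float(values.mean())
        sd[name] = float(values.std())  # population form (divisor n)
        if mean[name] == 0:
            warnings.warn(f"zero mean for {name}; CV undefined", stacklevel=2)
            cv[name] = float("nan")
        else:
            cv[name] = 100.0 * sd[name] / mean[name]
    return RunSummary(per_run=tuple(per_run), mean=mean, sd=sd, cv=cv)


def random_segregation_test(
    group_a: SpectraSet,
    group_b: SpectraSet,
    arch,
    train_config,
    n_runs: int = 10,
    mode: str = "fold-models",
    fold_results=None,
) -> tuple[RunSummary, list[ConfusionMatrix]]:
    """Repeated-evaluation robustness protocol.

    ``fold-models`` (default): run stratified k-fold cross-validation on group
    A once and evaluate each of the fold-trained models on all of group B —
    run i uses the fold-i model.  Pass ``fold_results`` from an earlier
    ``train_cv`` call to reuse already-trained fold models.  ``retrain``:
    train a fresh model on all of group A per run (new seed each run) and
    evaluate it on group B.  Returns the per-run summary and the per-run
    confusion matrices.
    """
    from .cnn import predict, train_cv, train_single  # local import: heavy module

    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    class_order = tuple(group_a.classes)
    matrices: list[ConfusionMatrix] = []
    metrics: list[RunMetrics] = []

    if mode == "fold-models":
        if n_runs > train_config.n_folds:
            raise ValueError("n_runs cannot exceed n_folds in fold-models mode")
        if fold_results is None:
            fold_results = train_cv(group_a, arch, train_config)
        models = [fr.model_ref for fr in fold_results[:n_runs]]
    elif mode == "retrain":
        models = [
            train_single(group_a, arch, train_config, seed_offset=run) for run in range(n_runs)
        ]
    else:
        raise ValueError("mode must be 'fold-models' or 'retrain'")

    for model in models:
        labels, _ = predict(model, group_b.absorbance)
        cm = confusion_matrix(group_b.labels, labels, class_order)
        matrices.append(cm)
        metrics.append(run_metrics(cm))
    return summarize_runs(metrics), matrices
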