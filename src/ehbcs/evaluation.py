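"""Wrapper fitness, cross-validated classification, metrics and benchmarking.

A feature subset is scored by the cross-validated accuracy of a classifier
trained on exactly those columns, combined with a feature-reduction bonus:

    f = beta * (d - s) / d + (1 - beta) * acc,     beta = 0.2 by default,

where d is the total feature count and s the subset size. At equal accuracy
the smaller subset wins; with beta = 0 the fitness is plain accuracy.

The classifier is an SVM by convention (RBF kernel for low-dimensional sets,
linear for high-dimensional ones); a fast nearest-centroid surrogate is
provided for oracle enumeration and tests, where tens of thousands of CV
evaluations make a full SVM impractical. Per-fold confusion counts are
averaged into accuracy, sensitivity, specificity, precision and F-measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .dataio import Dataset, FoldPlan, make_folds

__all__ = [
    "FitnessConfig",
    "FoldMetrics",
    "MetricReport",
    "BenchmarkReport",
    "CentroidClassifier",
    "confusion_metrics",
    "cv_evaluate",
    "fitness",
    "benchmark",
]


@dataclass
class FitnessConfig:
    """Parameters of the wrapper fitness and its internal cross-validation."""

    beta: float = 0.2
    classifier: str = "surrogate_centroid"
    k_folds: int | None = None
    positive_label: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must be in [0, 1]")
        if self.classifier not in ("svm_linear", "svm_rbf", "surrogate_centroid"):
            raise ValueError(f"unknown classifier {self.classifier!r}")


@dataclass
class FoldMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    undefined: tuple[str, ...] = ()


@dataclass
class MetricReport:
    """Per-fold confusion metrics and their across-fold averages."""

    folds: list[FoldMetrics]
    avg_acc: float
    avg_se: float
    avg_sp: float
    avg_pre: float
    avg_f1: float


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> FoldMetrics:
    """Single-fold metrics from confusion counts.

    Ratios with a zero denominator are reported as 0 and flagged in
    ``undefined`` rather than dropped, so every fold always contributes a
    numeric value.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total < 1:
        raise ValueError("empty fold")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / total
    se = ratio(tp, tp + fn, "sensitivity")
    sp = ratio(tn, fp + tn, "specificity")
    pre = ratio(tp, tp + fp, "precision")
    f1 = ratio(2 * pre * se, pre + se, "f1")
    return FoldMetrics(tp, tn, fp, fn, acc, se, sp, pre, f1, tuple(undefined))


class CentroidClassifier:
    """Minimal nearest-centroid classifier (Euclidean), pure numpy.

    Used as the fast surrogate inside the wrapper fitness loop: fitting is a
    pair of class means, prediction a two-distance comparison, which keeps
    exhaustive-subset oracle enumeration and property tests cheap. Ties go
    to class 0.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CentroidClassifier":
        self.centroids_ = np.stack([X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        d0 = ((X - self.centroids_[0]) ** 2).sum(axis=1)
        d1 = ((X - self.centroids_[1]) ** 2).sum(axis=1)
        return (d1 < d0).astype(int)


def _make_classifier(name: str):
    if name == "surrogate_centroid":
        return CentroidClassifier()
    if name == "svm_linear":
        return SVC(kernel="linear", C=1.0)
    if name == "svm_rbf":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    raise ValueError(f"unknown classifier {name!r}")


def default_kernel_for(d: int) -> str:
    """Kernel convention by dimensionality: RBF for low-d, linear for high-d."""
    return "svm_rbf" if d < 2000 else "svm_linear"


def cv_evaluate(
    data: Dataset,
    bits: np.ndarray,
    config: FitnessConfig | None = None,
    seed: int = 0,
    fold_plan: FoldPlan | None = None,
) -> MetricReport:
    """Cross-validate a classifier on the selected feature columns.

    Trains on each fold's complement and tests on the fold, restricted to
    the columns where ``bits`` is 1; deterministic given the fold plan (or
    seed) and classifier settings.
    """
    config = config or FitnessConfig()
    bits = np.asarray(bits)
    if bits.sum() < 1:
        raise ValueError("empty feature subset")
    if fold_plan is None:
        fold_plan = make_folds(data, k_override=config.k_folds, seed=seed)
    cols = np.flatnonzero(bits)
    X = data.features[:, cols]
    y = data.labels
    pos = config.positive_label
    folds = []
    for fold in range(fold_plan.k):
        tr, te = fold_plan.train_indices(fold), fold_plan.test_indices(fold)
        clf = _make_classifier(config.classifier)
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        truth = y[te]
        tp = int(((pred == pos) & (truth == pos)).sum())
        tn = int(((pred != pos) & (truth != pos)).sum())
        fp = int(((pred == pos) & (truth != pos)).sum())
        fn = int(((pred != pos) & (truth == pos)).sum())
        folds.append(confusion_metrics(tp, tn, fp, fn))
    k = len(folds)
    return MetricReport(
        folds=folds,
        avg_acc=sum(m.accuracy for m in folds) / k,
        avg_se=sum(m.sensitivity for m in folds) / k,
        avg_sp=sum(m.specificity for m in folds) / k,
        avg_pre=sum(m.precision for m in folds) / k,
        avg_f1=sum(m.f1 for m in folds) / k,
    )


def fitness(
    data: Dataset,
    bits: np.ndarray,
    config: FitnessConfig | None = None,
    seed: int = 0,
    fold_plan: FoldPlan | None = None,
) -> float:
    """Wrapper fitness f = beta (d - s)/d + (1 - beta) acc, in (0, 1]."""
    config = config or FitnessConfig()
    bits = np.asarray(bits)
    s = int(bits.sum())
    if s == 0:
        raise ValueError("empty feature subset")
    d = len(bits)
    acc = cv_evaluate(data, bits, config, seed=seed, fold_plan=fold_plan).avg_acc
    return config.beta * (d - s) / d + (1 - config.beta) * acc


class SubsetFitness:
    """Callable bits -> fitness, binding a dataset, fold plan and config.

    The fold plan is fixed at construction so every subset evaluated in a
    search (and every algorithm sharing the instance) sees the same folds.
    """

    def __init__(
        self,
        data: Dataset,
        config: FitnessConfig | None = None,
        seed: int = 0,
        fold_plan: FoldPlan | None = None,
    ):
        self.data = data
        self.config = config or FitnessConfig()
        self.fold_plan = fold_plan or make_folds(
            data, k_override=self.config.k_folds, seed=seed
        )

    def __call__(self, bits: np.ndarray) -> float:
        return fitness(self.data, bits, self.config, fold_plan=self.fold_plan)

    def report(self, bits: np.ndarray) -> MetricReport:
        return cv_evaluate(self.data, bits, self.config, fold_plan=self.fold_plan)


@dataclass
class BenchmarkReport:
    """Aggregated repeated-run results, one row per algorithm plus an Avg row.

    Columns follow the conventional layout: Avgacc, Max, Min, Std (population
    standard deviation over run accuracies), AvgN (mean subset size), SE, SP,
    Pre, F1, SR (size-reduction percentage).
    """

    table: pd.DataFrame
    runs: dict = field(default_factory=dict)

    def to_markdown(self) -> str:
        return self.table.to_markdown(floatfmt=".3f")


def benchmark(
    data: Dataset,
    algorithms=("ehbcs", "bga", "bpso"),
    n_runs: int = 5,
    seed: int = 0,
    fitness_config: FitnessConfig | None = None,
    **selector_kwargs,
) -> BenchmarkReport:
    """Run each algorithm ``n_runs`` times (seeds seed..seed+n_runs-1) and
    aggregate accuracy and subset-size statistics.

    The CV fold plan is built once and shared across algorithms and runs so
    comparisons are paired. Each run's best subset is re-evaluated with the
    same fold plan to produce its reported accuracy and confusion metrics.
    """
    from .optimizers import make_selector

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    fitness_config = fitness_config or FitnessConfig()
    fold_plan = make_folds(data, k_override=fitness_config.k_folds, seed=seed)
    fit_fn = SubsetFitness(data, fitness_config, fold_plan=fold_plan)
    d = data.n_features
    rows = []
    runs: dict = {}
    for algo in algorithms:
        accs, sizes, se, sp, pre, f1 = [], [], [], [], [], []
        runs[algo] = []
        for r in range(n_runs):
            sel = make_selector(algo, random_state=seed + r, **selector_kwargs)
            sel.set_params(fitness_fn=fit_fn)
            sel.fit(data.features, data.labels)
            bits = sel.get_support().astype(np.int8)
            rep = fit_fn.report(bits)
            accs.append(rep.avg_acc)
            sizes.append(int(bits.sum()))
            se.append(rep.avg_se)
            sp.append(rep.avg_sp)
            pre.append(rep.avg_pre)
            f1.append(rep.avg_f1)
            runs[algo].append(sel.result_)
        avg_n = float(np.mean(sizes))
        rows.append(
            {
                "Algorithm": algo.upper(),
                "Avgacc": float(np.mean(accs)),
                "Max": float(np.max(accs)),
                "Min": float(np.min(accs)),
                "Std": float(np.std(accs)),  # population convention
                "AvgN": avg_n,
                "SE": float(np.mean(se)),
                "SP": float(np.mean(sp)),
                "Pre": float(np.mean(pre)),
                "F1": float(np.mean(f1)),
                "SR": (d - avg_n) / d * 100.0,
            }
        )
    table = pd.DataFrame(rows)
    avg_row = table.drop(columns=["Algorithm"]).mean().to_dict()
    avg_row["Algorithm"] = "Avg"
    table = pd.concat([table, pd.DataFrame([avg_row])], ignore_index=True)
    table = table[
        ["Algorithm", "Avgacc", "Max", "Min", "Std", "AvgN", "SE", "SP", "Pre", "F1", "SR"]
    ]
    return BenchmarkReport(table=table, runs=runs)
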