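"""Loading, validation, normalization, fold construction and synthetic data.

A :class:`Dataset` is the universe a feature selector searches over: an
``n x d`` numeric matrix, a binary label vector in ``{0, 1}``, and feature /
case names for reporting. Loaders accept CSV (header row, one label column)
and LIBSVM/SVMlight sparse text. Cross-validation folds follow the rule that
small studies (fewer than 100 cases) get 5 folds and larger ones get 10, and
are always stratified so no fold loses a class.

The synthetic generator plants a configurable number of informative features
(class-conditional Gaussian mean shift), optional redundant copies of them,
and pure-noise features — a stand-in for the UCI / microarray style of
two-class tabular data this kind of selector is benchmarked on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.datasets import load_svmlight_file
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Dataset",
    "FoldPlan",
    "SyntheticSpec",
    "load_dataset",
    "write_csv",
    "normalize_features",
    "fold_count_for",
    "make_folds",
    "generate_synthetic",
]


@dataclass
class Dataset:
    """A two-class tabular dataset.

    Attributes
    ----------
    features : ndarray of shape (n, d)
        Numeric feature matrix, no missing values.
    labels : ndarray of shape (n,)
        Class labels in ``{0, 1}``.
    feature_names : list of str
        Unique names, length d.
    case_ids : list of str
        Row identifiers, length n.
    label_mapping : dict
        Original label value -> {0, 1}; the lexicographically smaller
        original label maps to 0 so sensitivity/specificity orientation
        is auditable.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    case_ids: list[str]
    label_mapping: dict = field(default_factory=dict)
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, d = self.features.shape
        if n < 2:
            raise ValueError("need at least 2 cases")
        if d < 1:
            raise ValueError("need at least 1 feature")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of cases")
        uniq = set(np.unique(self.labels).tolist())
        if uniq != {0, 1}:
            raise ValueError("not a binary-label dataset")
        self.labels = self.labels.astype(int)
        if np.isnan(self.features).any():
            raise ValueError("missing values in feature matrix")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must equal d")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature_names must be unique")
        if len(self.case_ids) != n:
            raise ValueError("case_ids length must equal n")

    @property
    def n_cases(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class FoldPlan:
    """Assignment of every case to exactly one of k stratified folds."""

    k: int
    assignments: np.ndarray

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        counts = np.bincount(self.assignments, minlength=self.k)
        if len(counts) != self.k or (counts == 0).any():
            raise ValueError("every fold must be non-empty")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass
class SyntheticSpec:
    """Recipe for a planted-signal two-class dataset.

    ``effect_size`` is the standardized class-mean shift of each informative
    feature (unit within-class SD). Redundant features are noisy copies of
    informative ones; all remaining features are N(0, 1) noise in both
    classes.
    """

    n: int = 200
    d: int = 50
    n_informative: int = 5
    effect_size: float = 2.0
    n_redundant: int = 0
    noise_sd: float = 0.1
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.d:
            raise ValueError("n_informative + n_redundant must be <= d")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")


def _map_labels(raw: np.ndarray) -> tuple[np.ndarray, dict]:
    values = sorted(set(raw.tolist()), key=str)
    if len(values) != 2:
        raise ValueError("not a binary-label dataset")
    mapping = {values[0]: 0, values[1]: 1}
    return np.array([mapping[v] for v in raw.tolist()]), mapping


def load_dataset(path, format: str = "csv", label_column="label") -> Dataset:
    """Load a labeled table from CSV or LIBSVM/SVMlight text.

    Labels are remapped to {0, 1} (mapping recorded on the Dataset); row
    order is preserved.
    """
    if format == "csv":
        frame = pd.read_csv(path, float_precision="round_trip")
        if isinstance(label_column, int):
            label_column = frame.columns[label_column]
        if label_column not in frame.columns:
            raise ValueError(f"label column {label_column!r} not found")
        raw_labels = frame[label_column].to_numpy()
        feats = frame.drop(columns=[label_column])
        for col in feats.columns:
            if not pd.api.types.is_numeric_dtype(feats[col]):
                bad = feats[~feats[col].apply(np.isreal)].index
                row = int(bad[0]) if len(bad) else 0
                raise ValueError(
                    f"non-numeric feature value in column {col!r}, row {row}"
                )
        labels, mapping = _map_labels(raw_labels)
        return Dataset(
            features=feats.to_numpy(dtype=float),
            labels=labels,
            feature_names=[str(c) for c in feats.columns],
            case_ids=[str(i) for i in frame.index],
            label_mapping=mapping,
        )
    if format == "libsvm":
        X, y = load_svmlight_file(str(path))
        X = np.asarray(X.todense(), dtype=float)
        labels, mapping = _map_labels(y)
        d = X.shape[1]
        return Dataset(
            features=X,
            labels=labels,
            feature_names=[f"f{j + 1}" for j in range(d)],
            case_ids=[str(i) for i in range(X.shape[0])],
            label_mapping=mapping,
        )
    raise ValueError(f"unknown format {format!r}")


def write_csv(data: Dataset, path, label_column: str = "label") -> None:
    """Write a Dataset back to CSV at full precision (round-trip safe)."""
    frame = pd.DataFrame(data.features, columns=data.feature_names)
    frame[label_column] = data.labels
    frame.to_csv(path, index=False, float_format="%.17g")


def normalize_features(data: Dataset, method: str = "minmax") -> Dataset:
    """Rescale features; ``minmax`` maps each non-constant feature to [0, 1].

    Constant features map to 0. ``zscore`` centers and scales by SD
    (constant features again map to 0). ``none`` returns the dataset
    unchanged.
    """
    if method == "none":
        return data
    X = data.features
    if method == "minmax":
        lo = X.min(axis=0)
        span = X.max(axis=0) - lo
        span_safe = np.where(span == 0, 1.0, span)
        Xn = (X - lo) / span_safe
        Xn[:, span == 0] = 0.0
    elif method == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd == 0, 1.0, sd)
        Xn = (X - mu) / sd_safe
        Xn[:, sd == 0] = 0.0
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return Dataset(
        features=Xn,
        labels=data.labels.copy(),
        feature_names=list(data.feature_names),
        case_ids=list(data.case_ids),
        label_mapping=dict(data.label_mapping),
        normalization=method,
    )


def fold_count_for(n_cases: int) -> int:
    """Fold-count rule: 5 folds below 100 cases, 10 folds otherwise."""
    return 5 if n_cases < 100 else 10


def make_folds(data_or_labels, k_override: int | None = None, seed: int = 0) -> FoldPlan:
    """Build a stratified, seed-deterministic fold plan.

    ``k`` follows :func:`fold_count_for` unless overridden. Raises if k
    exceeds the smaller class size (stratification impossible).
    """
    labels = (
        data_or_labels.labels
        if isinstance(data_or_labels, Dataset)
        else np.asarray(data_or_labels, dtype=int)
    )
    n = len(labels)
    k = int(k_override) if k_override is not None else fold_count_for(n)
    smallest = int(np.bincount(labels).min())
    if k > smallest:
        raise ValueError("insufficient cases for stratified folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments)


def generate_synthetic(spec: SyntheticSpec) -> tuple[Dataset, set[int]]:
    """Generate a planted-signal dataset; returns it with the ground truth.

    Informative features are N(0,1) in class 0 and N(effect_size, 1) in
    class 1; redundant features copy an informative one plus
    N(0, noise_sd) noise; everything else is N(0,1) in both classes.
    Column positions are shuffled so signal location carries no information.
    The returned set holds the informative feature indices (redundant
    columns excluded).
    """
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n) < spec.class_balance).astype(int)
    # both classes must be represented for a two-class problem
    for cls in (0, 1):
        if not (labels == cls).any():
            labels[rng.integers(spec.n)] = cls
    X = rng.standard_normal((spec.n, spec.d))
    for j in range(spec.n_informative):
        X[labels == 1, j] += spec.effect_size
    for r in range(spec.n_redundant):
        src = r % max(spec.n_informative, 1)
        X[:, spec.n_informative + r] = X[:, src] + spec.noise_sd * rng.standard_normal(
            spec.n
        )
    perm = rng.permutation(spec.d)
    X = X[:, perm]
    position = np.empty(spec.d, dtype=int)
    position[perm] = np.arange(spec.d)
    informative = {int(position[j]) for j in range(spec.n_informative)}
    kinds = np.full(spec.d, "noise", dtype=object)
    kinds[[position[j] for j in range(spec.n_informative)]] = "informative"
    kinds[
        [position[spec.n_informative + r] for r in range(spec.n_redundant)]
    ] = "redundant"
    data = Dataset(
        features=X,
        labels=labels,
        feature_names=[f"{kinds[j]}_{j}" for j in range(spec.d)],
        case_ids=[f"case_{i}" for i in range(spec.n)],
        label_mapping={0: 0, 1: 1},
    )
    return data, informative
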