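"""Relief feature weighting for two-class data.

Relief scores each feature by how well it separates a case from its nearest
neighbour of the other class (the *nearest miss*, NM) relative to its nearest
neighbour of the same class (the *nearest hit*, NH). For a sampled case x the
weight of feature j is updated as

    w_j <- w_j + |x_j - NM(x)_j| / T - |x_j - NH(x)_j| / T

over T sampled cases. A feature that differs across the class boundary but
not within a class accumulates positive weight; a feature whose value varies
within a class more than across classes goes negative, flagging it as
unhelpful for classification. The k-neighbour variant averages the update
over the k nearest hits and the k nearest misses.

These weights drive the selection pressure of the weighted binary cuckoo
search: the per-feature transfer-function coefficient gamma is taken from w,
so heavier features are more likely to enter candidate subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .dataio import Dataset

__all__ = ["ReliefConfig", "FeatureWeights", "compute_weights", "weights_to_gamma"]


@dataclass
class ReliefConfig:
    """Relief run parameters.

    T is the number of case-sampling iterations; with ``sampling="all_cases"``
    every case is visited once and T equals n (the deterministic convention).
    ``k`` only applies to the ``knn`` variant (default 3).
    """

    T: int | None = None
    k: int = 3
    variant: str = "nearest"
    sampling: str = "all_cases"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T is not None and self.T < 1:
            raise ValueError("T must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.variant not in ("nearest", "knn"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.sampling not in ("random", "all_cases"):
            raise ValueError(f"unknown sampling {self.sampling!r}")


@dataclass
class FeatureWeights:
    """Per-feature Relief weights; entries may be negative."""

    w: np.ndarray
    variant: str = "nearest"
    config: ReliefConfig = field(default_factory=ReliefConfig)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.isfinite(self.w).all():
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return len(self.w)

    def to_frame(self, feature_names=None):
        import pandas as pd

        names = feature_names or [f"f{j}" for j in range(len(self.w))]
        return pd.DataFrame({"feature_name": names, "weight": self.w})


def compute_weights(data: Dataset, config: ReliefConfig | None = None) -> FeatureWeights:
    """Run Relief (nearest-neighbour or k-NN variant) on a two-class dataset.

    Neighbour search is Euclidean over all features, the sampled case is
    excluded from its own hit search, and distance ties break to the lowest
    case index so results are reproducible. Deterministic given the seed
    (or unconditionally with ``sampling="all_cases"``).
    """
    config = config or ReliefConfig()
    X, y = data.features, data.labels
    n, d = X.shape
    counts = np.bincount(y, minlength=2)
    # the sampled case is excluded from its own hit search, so a class needs
    # one extra case beyond the neighbours requested
    need = 2 if config.variant == "nearest" else config.k + 1
    if counts.min() < need:
        raise ValueError("insufficient class support")

    lo, hi = X.min(), X.max()
    if lo < -1e-9 or hi > 1 + 1e-9:
        warnings.warn(
            "features are outside [0, 1]; Relief distances are scale-sensitive, "
            "consider min-max normalization",
            stacklevel=2,
        )

    if config.sampling == "all_cases":
        picks = np.arange(n)
    else:
        T = config.T if config.T is not None else n
        rng = np.random.default_rng(config.seed)
        picks = rng.integers(0, n, size=T)
    T = len(picks)

    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    same = y[:, None] == y[None, :]

    w = np.zeros(d)
    for i in picks:
        hit_dist = np.where(same[i], dist[i], np.inf)
        miss_dist = np.where(~same[i], dist[i], np.inf)
        if config.variant == "nearest":
            nh = int(np.argmin(hit_dist))
            nm = int(np.argmin(miss_dist))
            w += np.abs(X[i] - X[nm]) / T - np.abs(X[i] - X[nh]) / T
        else:
            k = config.k
            hits = np.argsort(hit_dist, kind="stable")[:k]
            misses = np.argsort(miss_dist, kind="stable")[:k]
            w += np.abs(X[i] - X[misses]).sum(axis=0) / (T * k)
            w -= np.abs(X[i] - X[hits]).sum(axis=0) / (T * k)
    return FeatureWeights(w=w, variant=config.variant, config=config)


def weights_to_gamma(
    weights: FeatureWeights | np.ndarray,
    scaling: str = "identity",
    clip_range: tuple[float, float] = (-1.0, 1.0),
) -> np.ndarray:
    """Map Relief weights to the transfer-function coefficients gamma.

    ``identity`` uses the weights as-is (gamma_j = w_j, the default);
    ``minmax`` rescales the weight range onto [-1, 1]; ``clip`` truncates
    to ``clip_range``.
    """
    w = weights.w if isinstance(weights, FeatureWeights) else np.asarray(weights, float)
    if scaling == "identity":
        return w.copy()
    if scaling == "minmax":
        lo, hi = w.min(), w.max()
        if hi == lo:
            return np.zeros_like(w)
        return 2.0 * (w - lo) / (hi - lo) - 1.0
    if scaling == "clip":
        return np.clip(w, *clip_range)
    raise ValueError(f"unknown scaling {scaling!r}")
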