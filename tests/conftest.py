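import numpy as np
import pytest

from ehbcs import (
    Dataset,
    FitnessConfig,
    SubsetFitness,
    SyntheticSpec,
    generate_synthetic,
    make_folds,
    normalize_features,
)


@pytest.fixture(scope="session")
def planted_data():
    """n=200, d=50 planted-signal dataset with 5 informative features."""
    data, truth = generate_synthetic(
        SyntheticSpec(n=200, d=50, n_informative=5, effect_size=2.0, seed=1)
    )
    return data, truth


@pytest.fixture(scope="session")
def small_planted_data():
    """n=60, d=12 dataset, cheap enough for exhaustive / repeated runs."""
    data, truth = generate_synthetic(
        SyntheticSpec(n=60, d=12, n_informative=3, effect_size=1.5, seed=3)
    )
    return data, truth


@pytest.fixture(scope="session")
def separable_data():
    """d=8 dataset whose first feature equals the label: a perfect
    single-feature solution exists by construction."""
    rng = np.random.default_rng(7)
    n = 60
    labels = np.tile([0, 1], n // 2)
    # low-amplitude noise keeps the label-valued feature dominant for any
    # classifier, so supersets of {0} stay perfectly separable too
    X = 0.1 * rng.standard_normal((n, 8))
    X[:, 0] = labels.astype(float)
    return Dataset(
        features=X,
        labels=labels,
        feature_names=[f"f{j}" for j in range(8)],
        case_ids=[str(i) for i in range(n)],
    )


@pytest.fixture(scope="session")
def surrogate_fitness(small_planted_data):
    """Shared-fold wrapper fitness on the small dataset (fast surrogate)."""
    data, _ = small_planted_data
    datan = normalize_features(data)
    plan = make_folds(datan, seed=0)
    return SubsetFitness(datan, FitnessConfig(), fold_plan=plan)


def brute_force_relief(X, y, variant="nearest", k=1):
    """Independent double-loop Relief used as the oracle in tests.

    Pure-Python nested loops; shares no code with the package
    implementation. Visits every case once (the all_cases convention),
    Euclidean neighbour search, ties to the lowest case index, the case
    excluded from its own hit search.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    T = n
    w = [0.0] * d
    for i in range(n):
        hits, misses = [], []
        for j in range(n):
            if j == i:
                continue
            dist = sum((X[i, a] - X[j, a]) ** 2 for a in range(d)) ** 0.5
            (hits if y[j] == y[i] else misses).append((dist, j))
        hits.sort()
        misses.sort()
        if variant == "nearest":
            nh = hits[0][1]
            nm = misses[0][1]
            for a in range(d):
                w[a] += abs(X[i, a] - X[nm, a]) / T - abs(X[i, a] - X[nh, a]) / T
        else:
            for a in range(d):
                for _, z in misses[:k]:
                    w[a] += abs(X[i, a] - X[z, a]) / (T * k)
                for _, z in hits[:k]:
                    w[a] -= abs(X[i, a] - X[z, a]) / (T * k)
    return np.array(w)
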