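"""Binary metaheuristic feature selectors with a scikit-learn interface.

Four population-based searches over d-bit feature-inclusion vectors, all
maximizing the wrapper fitness (cross-validated accuracy plus a
feature-reduction bonus):

``EHBCSSelector``
    Elite hybrid binary cuckoo search. Relief weights are computed first and
    become the per-feature transfer-function coefficients, so discriminative
    features are more likely to be switched on by a Lévy step. Each
    iteration the elite nest is held fixed, every other nest is re-binarized
    from a fresh Lévy flight (kept only on improvement), and the worst
    nests are regenerated by roulette selection + single-point crossover in
    place of the classical abandonment step.
``BCSSelector``
    Plain binary cuckoo search: unit sigmoid coefficient, no crossover, the
    worst fraction p_a of nests re-randomized each iteration.
``BGASelector``
    Generational binary genetic algorithm (roulette selection, single-point
    crossover, per-bit mutation, elitism of one).
``BPSOSelector``
    Binary particle swarm optimization (velocity update with inertia and
    cognitive/social pulls, sigmoid bit sampling, personal/global bests).

All selectors implement ``fit(X, y)`` / ``transform`` via ``SelectorMixin``
and are reproducible from ``random_state``; independent RNG streams are
split per component (initialization, per-nest Lévy flights, genetic
operators) so changing one knob does not perturb the others' draws.
"""

from __future__ import annotations

import time
from abc import abstractmethod
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .dataio import Dataset
from .evaluation import FitnessConfig, SubsetFitness
from .genetic_ops import Nest, Population, apply_elite_regeneration, roulette_select, single_point_crossover
from .levy_binary import LevyConfig, binarize, sample_steps
from .relief import FeatureWeights, ReliefConfig, compute_weights, weights_to_gamma

__all__ = [
    "SearchConfig",
    "RunResult",
    "EHBCSSelector",
    "BCSSelector",
    "BGASelector",
    "BPSOSelector",
    "make_selector",
    "run_ehbcs",
    "run_bcs",
    "run_bga",
    "run_bpso",
]


@dataclass
class RunResult:
    """Outcome of one search run.

    ``trajectory`` holds the best-so-far fitness at the end of each
    iteration (length n_iter); ``initial_best_fitness`` is the best of the
    random initial population, so ``best_fitness`` is defined even for
    n_iter = 0.
    """

    best_bits: np.ndarray
    best_fitness: float
    initial_best_fitness: float
    trajectory: np.ndarray
    n_evaluations: int
    n_cache_hits: int
    selected_indices: np.ndarray
    config: dict
    seed: int | None
    wall_time: float

    def to_dict(self) -> dict:
        # wall_time deliberately omitted: serialized results are
        # byte-reproducible given the same config and seed
        return {
            "best_bits": self.best_bits.astype(int).tolist(),
            "best_fitness": self.best_fitness,
            "initial_best_fitness": self.initial_best_fitness,
            "trajectory": np.asarray(self.trajectory, float).tolist(),
            "n_evaluations": self.n_evaluations,
            "n_cache_hits": self.n_cache_hits,
            "selected_indices": self.selected_indices.astype(int).tolist(),
            "config": self.config,
            "seed": self.seed,
        }


class _CountingCache:
    """Fitness memo keyed by the bit string; counts distinct evaluations."""

    def __init__(self, fn):
        self.fn = fn
        self.cache: dict[bytes, float] = {}
        self.n_evaluations = 0
        self.n_cache_hits = 0

    def __call__(self, bits: np.ndarray) -> float:
        key = np.asarray(bits, dtype=np.int8).tobytes()
        if key in self.cache:
            self.n_cache_hits += 1
            return self.cache[key]
        val = float(self.fn(bits))
        self.n_evaluations += 1
        self.cache[key] = val
        return val


def _random_population(d, n_pop, rng, repair) -> list[Nest]:
    nests = []
    for _ in range(n_pop):
        bits = (rng.random(d) < 0.5).astype(np.int8)
        bits = repair(bits, rng)
        nests.append(Nest(bits))
    return nests


def _repair_random(bits: np.ndarray, rng) -> np.ndarray:
    """Empty-subset repair for unweighted searches: set one random bit."""
    if bits.sum() == 0:
        bits = bits.copy()
        bits[rng.integers(len(bits))] = 1
    return bits


class BaseBinarySelector(SelectorMixin, BaseEstimator):
    """Shared fit plumbing for the population-based binary selectors.

    Subclasses implement ``_search``. The wrapper fitness defaults to
    cross-validated accuracy of the configured classifier plus the
    reduction bonus; passing ``fitness_fn`` (any callable bits -> float)
    overrides it, which is how oracle tests and shared-fold benchmarks
    plug in.
    """

    def __init__(
        self,
        n_pop=30,
        n_iter=100,
        beta=0.2,
        classifier="surrogate_centroid",
        k_folds=None,
        normalize="minmax",
        fitness_fn=None,
        random_state=None,
    ):
        self.n_pop = n_pop
        self.n_iter = n_iter
        self.beta = beta
        self.classifier = classifier
        self.k_folds = k_folds
        self.normalize = normalize
        self.fitness_fn = fitness_fn
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------
    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _more_tags(self):
        return {"requires_y": True, "binary_only": True}

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("not a binary-label dataset")
        y01 = (y == classes[1]).astype(int)
        if self.n_pop < 2:
            raise ValueError("n_pop must be >= 2")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")

        if self.normalize not in ("minmax", "zscore", "none"):
            raise ValueError(f"unknown normalization {self.normalize!r}")
        Xs = X
        if self.normalize == "minmax":
            lo = X.min(axis=0)
            span = X.max(axis=0) - lo
            span = np.where(span == 0, 1.0, span)
            Xs = (X - lo) / span
        elif self.normalize == "zscore":
            sd = X.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xs = (X - X.mean(axis=0)) / sd

        seed = self.random_state if self.random_state is not None else 0
        root = np.random.SeedSequence(seed)
        streams = {
            name: np.random.default_rng(child)
            for name, child in zip(
                ("init", "levy", "genetic", "velocity", "abandon"), root.spawn(5)
            )
        }
        streams["levy_root"] = root.spawn(1)[0]

        if self.fitness_fn is not None:
            base_fn = self.fitness_fn
        else:
            data = Dataset(
                features=Xs,
                labels=y01,
                feature_names=[f"f{j}" for j in range(X.shape[1])],
                case_ids=[str(i) for i in range(X.shape[0])],
            )
            base_fn = SubsetFitness(
                data,
                FitnessConfig(
                    beta=self.beta, classifier=self.classifier, k_folds=self.k_folds
                ),
                seed=seed,
            )
        cache = _CountingCache(base_fn)

        t0 = time.perf_counter()
        best_bits, init_best, trajectory = self._search(Xs, y01, cache, streams)
        wall = time.perf_counter() - t0

        trajectory = np.asarray(trajectory, dtype=float)
        best_fitness = float(trajectory[-1]) if len(trajectory) else float(init_best)
        self.n_features_in_ = X.shape[1]
        self.classes_ = classes
        self.support_ = best_bits.astype(bool)
        self.best_fitness_ = best_fitness
        self.trajectory_ = trajectory
        self.result_ = RunResult(
            best_bits=best_bits.astype(np.int8),
            best_fitness=best_fitness,
            initial_best_fitness=float(init_best),
            trajectory=trajectory,
            n_evaluations=cache.n_evaluations,
            n_cache_hits=cache.n_cache_hits,
            selected_indices=np.flatnonzero(best_bits),
            config={k: v for k, v in self.get_params().items() if k != "fitness_fn"},
            seed=self.random_state,
            wall_time=wall,
        )
        return self

    @abstractmethod
    def _search(self, X, y, fitness, streams):
        """Run the search; return (best_bits, initial_best_fitness, trajectory)."""


class EHBCSSelector(BaseBinarySelector):
    """Elite hybrid binary cuckoo search feature selector.

    Parameters follow the reference configuration: step scale ``alpha=1``,
    Lévy index ``levy_beta=1.5``, crossover probability ``p_c=0.5``,
    regenerated worst fraction ``p_r=0.3``, Relief neighbour count
    ``relief_k=3`` and population 30. ``relief_weights`` accepts
    precomputed weights (skipping the internal Relief pass);
    ``gamma_scaling`` controls how weights become sigmoid coefficients
    (identity by default).
    """

    def __init__(
        self,
        n_pop=30,
        n_iter=100,
        alpha=1.0,
        levy_beta=1.5,
        p_c=0.5,
        p_r=0.3,
        relief_k=3,
        relief_variant="knn",
        gamma_scaling="identity",
        acceptance="greedy",
        relief_weights=None,
        beta=0.2,
        classifier="surrogate_centroid",
        k_folds=None,
        normalize="minmax",
        fitness_fn=None,
        random_state=None,
    ):
        super().__init__(
            n_pop=n_pop,
            n_iter=n_iter,
            beta=beta,
            classifier=classifier,
            k_folds=k_folds,
            normalize=normalize,
            fitness_fn=fitness_fn,
            random_state=random_state,
        )
        self.alpha = alpha
        self.levy_beta = levy_beta
        self.p_c = p_c
        self.p_r = p_r
        self.relief_k = relief_k
        self.relief_variant = relief_variant
        self.gamma_scaling = gamma_scaling
        self.acceptance = acceptance
        self.relief_weights = relief_weights

    def _search(self, X, y, fitness, streams):
        d = X.shape[1]
        if self.relief_weights is not None:
            w = (
                self.relief_weights
                if isinstance(self.relief_weights, FeatureWeights)
                else FeatureWeights(np.asarray(self.relief_weights, float))
            )
            if len(w) != d:
                raise ValueError("relief_weights length must equal n_features")
        else:
            data = Dataset(
                features=X,
                labels=y,
                feature_names=[f"f{j}" for j in range(d)],
                case_ids=[str(i) for i in range(X.shape[0])],
            )
            w = compute_weights(
                data,
                ReliefConfig(
                    k=self.relief_k, variant=self.relief_variant, sampling="all_cases"
                ),
            )
        self.relief_weights_ = w
        gammas = weights_to_gamma(w, scaling=self.gamma_scaling)
        self.gammas_ = gammas
        top_gamma = int(np.argmax(gammas))

        def repair(bits, rng):
            # an empty subset has undefined fitness: fall back to the
            # heaviest feature
            if bits.sum() == 0:
                bits = bits.copy()
                bits[top_gamma] = 1
            return bits

        levy_cfg = LevyConfig(alpha=self.alpha, levy_beta=self.levy_beta)
        nest_rngs = [
            np.random.default_rng(s) for s in streams["levy_root"].spawn(self.n_pop)
        ]
        pop = Population(
            _random_population(d, self.n_pop, streams["init"], repair)
        )
        for nest in pop.nests:
            nest.fitness = fitness(nest.bits)
        pop.refresh_elite()
        init_best = pop.elite.fitness

        trajectory = []
        best = init_best
        for _ in range(self.n_iter):
            elite_idx = pop.elite_index
            for i, nest in enumerate(pop.nests):
                if i == elite_idx:
                    continue
                steps = sample_steps(d, levy_cfg, nest_rngs[i])
                newbits = binarize(steps, gammas, nest_rngs[i])
                newbits = repair(newbits, nest_rngs[i])
                f_new = fitness(newbits)
                if self.acceptance == "always" or f_new > nest.fitness:
                    nest.bits, nest.fitness = newbits, f_new
                    nest.provenance = "levy"
            apply_elite_regeneration(
                pop, self.p_c, self.p_r, streams["genetic"], fitness
            )
            best = max(best, pop.elite.fitness)
            trajectory.append(best)
        pop.refresh_elite()
        return pop.elite.bits.copy(), init_best, trajectory


class BCSSelector(BaseBinarySelector):
    """Plain binary cuckoo search baseline (unit sigmoid coefficient).

    No Relief weighting and no crossover; instead the worst fraction
    ``p_a`` of non-elite nests is abandoned and re-randomized each
    iteration, as in the classical formulation.
    """

    def __init__(
        self,
        n_pop=30,
        n_iter=100,
        alpha=1.0,
        levy_beta=1.5,
        p_a=0.25,
        acceptance="greedy",
        beta=0.2,
        classifier="surrogate_centroid",
        k_folds=None,
        normalize="minmax",
        fitness_fn=None,
        random_state=None,
    ):
        super().__init__(
            n_pop=n_pop,
            n_iter=n_iter,
            beta=beta,
            classifier=classifier,
            k_folds=k_folds,
            normalize=normalize,
            fitness_fn=fitness_fn,
            random_state=random_state,
        )
        self.alpha = alpha
        self.levy_beta = levy_beta
        self.p_a = p_a
        self.acceptance = acceptance

    def _search(self, X, y, fitness, streams):
        d = X.shape[1]
        gammas = np.ones(d)
        levy_cfg = LevyConfig(alpha=self.alpha, levy_beta=self.levy_beta)
        nest_rngs = [
            np.random.default_rng(s) for s in streams["levy_root"].spawn(self.n_pop)
        ]
        pop = Population(
            _random_population(d, self.n_pop, streams["init"], _repair_random)
        )
        for nest in pop.nests:
            nest.fitness = fitness(nest.bits)
        pop.refresh_elite()
        init_best = pop.elite.fitness

        abandon_rng = streams["abandon"]
        n_abandon = int(np.floor(self.p_a * (self.n_pop - 1)))
        trajectory = []
        best = init_best
        for _ in range(self.n_iter):
            elite_idx = pop.elite_index
            for i, nest in enumerate(pop.nests):
                if i == elite_idx:
                    continue
                steps = sample_steps(d, levy_cfg, nest_rngs[i])
                newbits = binarize(steps, gammas, nest_rngs[i])
                newbits = _repair_random(newbits, nest_rngs[i])
                f_new = fitness(newbits)
                if self.acceptance == "always" or f_new > nest.fitness:
                    nest.bits, nest.fitness = newbits, f_new
                    nest.provenance = "levy"
            pop.refresh_elite()
            if n_abandon:
                f = pop.fitnesses()
                non_elite = [i for i in range(self.n_pop) if i != pop.elite_index]
                worst = sorted(non_elite, key=lambda i: (f[i], -i))[:n_abandon]
                for i in worst:
                    bits = (abandon_rng.random(d) < 0.5).astype(np.int8)
                    bits = _repair_random(bits, abandon_rng)
                    pop.nests[i] = Nest(bits, fitness(bits), provenance="abandon")
                pop.refresh_elite()
            best = max(best, pop.elite.fitness)
            trajectory.append(best)
        pop.refresh_elite()
        return pop.elite.bits.copy(), init_best, trajectory


class BGASelector(BaseBinarySelector):
    """Generational binary genetic algorithm baseline.

    Roulette selection, single-point crossover with probability ``p_c``
    (default 0.8), per-bit mutation with probability ``p_m`` (default 0.1)
    and elitism of one.
    """

    def __init__(
        self,
        n_pop=30,
        n_iter=100,
        p_c=0.8,
        p_m=0.1,
        beta=0.2,
        classifier="surrogate_centroid",
        k_folds=None,
        normalize="minmax",
        fitness_fn=None,
        random_state=None,
    ):
        super().__init__(
            n_pop=n_pop,
            n_iter=n_iter,
            beta=beta,
            classifier=classifier,
            k_folds=k_folds,
            normalize=normalize,
            fitness_fn=fitness_fn,
            random_state=random_state,
        )
        self.p_c = p_c
        self.p_m = p_m

    def _search(self, X, y, fitness, streams):
        d = X.shape[1]
        rng = streams["genetic"]
        pop = Population(
            _random_population(d, self.n_pop, streams["init"], _repair_random)
        )
        for nest in pop.nests:
            nest.fitness = fitness(nest.bits)
        pop.refresh_elite()
        init_best = pop.elite.fitness

        trajectory = []
        best = init_best
        for _ in range(self.n_iter):
            elite = pop.elite.copy()
            children: list[Nest] = []
            while len(children) < self.n_pop - 1:
                i, j = roulette_select(pop, 2, rng)
                pa, pb = pop.nests[int(i)], pop.nests[int(j)]
                if d >= 2 and rng.random() < self.p_c:
                    c1, c2 = single_point_crossover(pa, pb, rng)
                else:
                    c1, c2 = pa.copy(), pb.copy()
                children.extend([c1, c2])
            children = children[: self.n_pop - 1]
            for child in children:
                flips = rng.random(d) < self.p_m
                if flips.any():
                    child.bits = np.where(flips, 1 - child.bits, child.bits).astype(
                        np.int8
                    )
                    child.fitness = None
                child.bits = _repair_random(child.bits, rng)
                child.fitness = fitness(child.bits)
            pop = Population([elite] + children)
            pop.refresh_elite()
            best = max(best, pop.elite.fitness)
            trajectory.append(best)
        pop.refresh_elite()
        return pop.elite.bits.copy(), init_best, trajectory


class BPSOSelector(BaseBinarySelector):
    """Binary particle swarm optimization baseline.

    Velocity update v <- omega v + c1 r1 (pbest - x) + c2 r2 (gbest - x),
    clamped to +-v_max (default 6); each bit is then resampled as 1 with
    probability sigmoid(v). Defaults c1=1, c2=2, omega=0.9.
    """

    def __init__(
        self,
        n_pop=30,
        n_iter=100,
        c1=1.0,
        c2=2.0,
        omega=0.9,
        v_max=6.0,
        beta=0.2,
        classifier="surrogate_centroid",
        k_folds=None,
        normalize="minmax",
        fitness_fn=None,
        random_state=None,
    ):
        super().__init__(
            n_pop=n_pop,
            n_iter=n_iter,
            beta=beta,
            classifier=classifier,
            k_folds=k_folds,
            normalize=normalize,
            fitness_fn=fitness_fn,
            random_state=random_state,
        )
        self.c1 = c1
        self.c2 = c2
        self.omega = omega
        self.v_max = v_max

    def _search(self, X, y, fitness, streams):
        d = X.shape[1]
        rng = streams["velocity"]
        positions = [
            _repair_random((streams["init"].random(d) < 0.5).astype(np.int8), streams["init"])
            for _ in range(self.n_pop)
        ]
        velocities = [np.zeros(d) for _ in range(self.n_pop)]
        fits = [fitness(x) for x in positions]
        pbest = [x.copy() for x in positions]
        pbest_f = list(fits)
        g = int(np.argmax(fits))
        gbest, gbest_f = positions[g].copy(), fits[g]
        init_best = gbest_f

        trajectory = []
        for _ in range(self.n_iter):
            for i in range(self.n_pop):
                r1, r2 = rng.random(d), rng.random(d)
                v = (
                    self.omega * velocities[i]
                    + self.c1 * r1 * (pbest[i] - positions[i])
                    + self.c2 * r2 * (gbest - positions[i])
                )
                velocities[i] = np.clip(v, -self.v_max, self.v_max)
                prob = 1.0 / (1.0 + np.exp(-velocities[i]))
                bits = (rng.random(d) <= prob).astype(np.int8)
                bits = _repair_random(bits, rng)
                positions[i] = bits
                f = fitness(bits)
                if f > pbest_f[i]:
                    pbest[i], pbest_f[i] = bits.copy(), f
                    if f > gbest_f:
                        gbest, gbest_f = bits.copy(), f
            trajectory.append(gbest_f)
        return gbest, init_best, trajectory


_SELECTORS = {
    "ehbcs": EHBCSSelector,
    "bcs": BCSSelector,
    "bga": BGASelector,
    "bpso": BPSOSelector,
}


@dataclass
class SearchConfig:
    """Algorithm choice plus its parameter block for the functional API."""

    algorithm: str = "ehbcs"
    n_pop: int = 30
    n_iter: int = 100
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in _SELECTORS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.n_pop < 2:
            raise ValueError("n_pop must be >= 2")


def make_selector(algorithm: str, **kwargs) -> BaseBinarySelector:
    """Instantiate a selector by name ('ehbcs', 'bcs', 'bga', 'bpso')."""
    if algorithm not in _SELECTORS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return _SELECTORS[algorithm](**kwargs)


def _run(algorithm, data: Dataset, config: SearchConfig | None, fitness_fn, **extra):
    config = config or SearchConfig(algorithm=algorithm)
    sel = make_selector(
        algorithm,
        n_pop=config.n_pop,
        n_iter=config.n_iter,
        random_state=config.seed,
        fitness_fn=fitness_fn,
        **{**config.params, **extra},
    )
    sel.fit(data.features, data.labels)
    return sel.result_


def run_ehbcs(
    data: Dataset,
    weights: FeatureWeights | None = None,
    config: SearchConfig | None = None,
    fitness_fn=None,
) -> RunResult:
    """Run the elite hybrid weighted cuckoo search once; thin wrapper over
    :class:`EHBCSSelector`."""
    return _run("ehbcs", data, config, fitness_fn, relief_weights=weights)


def run_bcs(data: Dataset, config=None, fitness_fn=None) -> RunResult:
    return _run("bcs", data, config, fitness_fn)


def run_bga(data: Dataset, config=None, fitness_fn=None) -> RunResult:
    return _run("bga", data, config, fitness_fn)


def run_bpso(data: Dataset, config=None, fitness_fn=None) -> RunResult:
    return _run("bpso", data, config, fitness_fn)
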