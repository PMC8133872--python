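"""Elitist genetic operators on nest populations.

The elite-hybrid search replaces classical cuckoo "discovery" (random
abandonment of poor nests) with genetic regeneration: the worst fraction of
non-elite nests is rebuilt from offspring of roulette-selected parents via
single-point crossover, while the single best nest (the elite) is copied
through untouched so the best fitness can never regress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Nest",
    "Population",
    "roulette_probabilities",
    "roulette_select",
    "single_point_crossover",
    "apply_elite_regeneration",
]


@dataclass
class Nest:
    """One candidate feature subset: a d-bit inclusion vector plus fitness."""

    bits: np.ndarray
    fitness: float | None = None
    provenance: str = "init"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def copy(self) -> "Nest":
        return Nest(self.bits.copy(), self.fitness, self.provenance)


@dataclass
class Population:
    """Fixed-size collection of nests with a designated elite (best) nest."""

    nests: list[Nest]
    elite_index: int = 0

    def fitnesses(self) -> np.ndarray:
        if any(n.fitness is None for n in self.nests):
            raise ValueError("population not fully evaluated")
        return np.array([n.fitness for n in self.nests], dtype=float)

    def refresh_elite(self) -> int:
        """Point elite_index at the best nest.

        Ties break toward fewer selected features, then lower index.
        """
        f = self.fitnesses()
        sizes = np.array([n.n_selected for n in self.nests])
        order = np.lexsort((np.arange(len(f)), sizes, -f))
        self.elite_index = int(order[0])
        return self.elite_index

    @property
    def elite(self) -> Nest:
        return self.nests[self.elite_index]


def roulette_probabilities(fitnesses) -> tuple[np.ndarray, np.ndarray]:
    """Selection probabilities p_i = f_i / sum(f) and their cumulative sums.

    Requires strictly positive fitness (the wrapper fitness lives in (0, 1]).
    The last cumulative entry is forced to exactly 1.
    """
    f = np.asarray(fitnesses, dtype=float)
    if (f <= 0).any():
        raise ValueError("roulette requires positive fitness")
    p = f / f.sum()
    q = np.cumsum(p)
    q[-1] = 1.0
    return p, q


def roulette_select(
    pop: Population | np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` nest indices with replacement, proportional to fitness."""
    f = pop.fitnesses() if isinstance(pop, Population) else np.asarray(pop, float)
    _, q = roulette_probabilities(f)
    draws = rng.random(count)
    return np.searchsorted(q, draws, side="left")


def single_point_crossover(
    a: Nest, b: Nest, rng: np.random.Generator, point: int | None = None
) -> tuple[Nest, Nest]:
    """Swap the suffixes of two equal-length bit strings after a random cut.

    The cut point is uniform on {1, ..., d-1}; offspring fitness is unset.
    """
    d = len(a.bits)
    if len(b.bits) != d:
        raise ValueError("parents must have equal bit length")
    if d < 2:
        raise ValueError("crossover needs at least 2 bits")
    c = int(rng.integers(1, d)) if point is None else int(point)
    if not 1 <= c <= d - 1:
        raise ValueError("crossover point out of range")
    child1 = np.concatenate([a.bits[:c], b.bits[c:]])
    child2 = np.concatenate([b.bits[:c], a.bits[c:]])
    return (
        Nest(child1, provenance="crossover"),
        Nest(child2, provenance="crossover"),
    )


def apply_elite_regeneration(
    pop: Population,
    p_c: float,
    p_r: float,
    rng: np.random.Generator,
    fitness_fn,
) -> Population:
    """Regenerate the worst non-elite nests from crossover offspring.

    floor(p_r * (n_pop - 1)) worst non-elite nests are replaced by offspring
    of roulette-selected parent pairs; each pair actually crosses over with
    probability p_c and is cloned otherwise. The elite nest is copied through
    untouched and elite_index is refreshed afterwards, so the best fitness
    never decreases. Population size is unchanged.
    """
    if not 0 <= p_c <= 1 or not 0 <= p_r <= 1:
        raise ValueError("p_c and p_r must be probabilities")
    pop.refresh_elite()
    n_pop = len(pop.nests)
    n_replace = int(np.floor(p_r * (n_pop - 1)))
    if n_replace == 0:
        return pop
    f = pop.fitnesses()
    non_elite = [i for i in range(n_pop) if i != pop.elite_index]
    worst = sorted(non_elite, key=lambda i: (f[i], -i))[:n_replace]

    offspring: list[Nest] = []
    while len(offspring) < n_replace:
        i, j = roulette_select(pop, 2, rng)
        pa, pb = pop.nests[int(i)], pop.nests[int(j)]
        if rng.random() < p_c:
            c1, c2 = single_point_crossover(pa, pb, rng)
        else:
            c1, c2 = pa.copy(), pb.copy()
            c1.provenance = c2.provenance = "clone"
            c1.fitness = pa.fitness
            c2.fitness = pb.fitness
        offspring.extend([c1, c2])
    for slot, child in zip(worst, offspring[:n_replace]):
        if child.fitness is None:
            child.fitness = float(fitness_fn(child.bits))
        pop.nests[slot] = child
    pop.refresh_elite()
    return pop
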