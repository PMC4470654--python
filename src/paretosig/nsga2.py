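"""Elitist multi-objective genetic algorithm (NSGA-II) over binary chromosomes.

The population holds fixed-length bit vectors; fitness is the Pareto front
index from fast non-dominated sorting, diversity is maintained with the
crowding distance, parents are drawn by k-way tournament, and survivors are
the top N of the merged parent+offspring pool (elitism). The run terminates
when the set of first-front bit patterns is unchanged for a configured
number of consecutive generations, or at a safety generation cap.

All randomness flows through a single ``numpy`` generator seeded from the
config, consumed in a fixed order (initialization, then per generation:
tournament draws, crossover, mutation, all-zero repairs), so runs are
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class GAConfig:
    population_size: int = 200
    tournament_size: int = 5
    crossover_prob: float = 0.8
    mutation_prob: float = 0.02      # per-bit flip probability
    init_set_fraction: float = 0.10  # expected fraction of 1-bits at initialization
    stagnation_generations: int = 200
    max_generations: int = 5000      # safety cap
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        for name in ("crossover_prob", "mutation_prob", "init_set_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")


@dataclass(eq=False)
class Individual:
    bits: np.ndarray                       # uint8 0/1 vector
    objectives: tuple | None = None        # (size, separation, relevance)
    rank: int = 0                          # 1 = first Pareto front
    crowding: float = 0.0

    @property
    def key(self) -> bytes:
        return self.bits.tobytes()


@dataclass
class GenerationStat:
    generation: int
    front_size: int
    mean_size: float
    mean_separation: float
    mean_relevance: float


@dataclass
class GARunResult:
    population: list[Individual]
    front: list[Individual]        # unique first-front individuals
    history: list[GenerationStat]
    generations: int
    terminated_by: str             # "stagnation" | "max_generations"


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def repair_all_zero(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """All-zero chromosomes are repaired by setting one uniformly random bit."""
    if not bits.any():
        bits[rng.integers(bits.size)] = 1
    return bits


def initialize_population(k: int, config: GAConfig,
                          rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """N chromosomes of length k, each bit set with probability init_set_fraction."""
    if k < 2:
        raise ValueError("chromosome length must be >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = (rng.random((config.population_size, k)) < config.init_set_fraction)
    out = []
    for row in pop.astype(np.uint8):
        out.append(repair_all_zero(row, rng))
    return out


def dominates(a, b) -> bool:
    """True iff a is better-or-equal in all objectives and strictly better in one."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return bool(np.all(a <= b) and np.any(a < b))


def fast_nondominated_sort(objectives) -> list[list[int]]:
    """Partition points into Pareto fronts (minimization); returns index lists.

    Front 1 is the non-dominated set; front r is non-dominated after removing
    fronts < r. Pairwise dominance is computed with vectorized comparisons.
    """
    objs = np.asarray(objectives, dtype=float)
    n = objs.shape[0]
    if n == 0:
        return []
    le = np.all(objs[:, None, :] <= objs[None, :, :], axis=-1)
    lt = np.any(objs[:, None, :] < objs[None, :, :], axis=-1)
    dom = le & lt                     # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    fronts: list[list[int]] = []
    assigned = np.zeros(n, dtype=bool)
    while not assigned.all():
        current = np.flatnonzero((n_dominators == 0) & ~assigned)
        fronts.append([int(i) for i in current])
        assigned[current] = True
        n_dominators = n_dominators - dom[current].sum(axis=0)
    return fronts


def crowding_distance(objectives) -> np.ndarray:
    """Crowding distances for one front.

    Fronts of at most two individuals get +inf everywhere. Otherwise, per
    objective, boundary individuals get +inf and interior ones accumulate the
    normalized neighbour gap; an objective with zero range contributes
    nothing (no gap, no boundary infinity).
    """
    objs = np.asarray(objectives, dtype=float)
    n = objs.shape[0]
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for m in range(objs.shape[1]):
        vals = objs[:, m]
        span = vals.max() - vals.min()
        if span == 0:
            continue
        order = np.argsort(vals, kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        gaps = (vals[order[2:]] - vals[order[:-2]]) / span
        dist[order[1:-1]] += gaps
    return dist


def tournament_winner(entrants: Sequence[Individual],
                      rng: np.random.Generator) -> Individual:
    """Lowest front rank wins; ties by larger crowding, remaining ties by rng."""
    best_key = min((e.rank, -e.crowding) for e in entrants)
    tied = [e for e in entrants if (e.rank, -e.crowding) == best_key]
    if len(tied) == 1:
        return tied[0]
    return tied[rng.integers(len(tied))]


def tournament_select(population: Sequence[Individual], config: GAConfig,
                      rng: np.random.Generator) -> Individual:
    """k-way tournament over uniform draws with replacement."""
    idx = rng.integers(len(population), size=config.tournament_size)
    return tournament_winner([population[i] for i in idx], rng)


def single_point_crossover(a: np.ndarray, b: np.ndarray, config: GAConfig,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """With probability crossover_prob, swap suffixes at a uniform cut in [1, K-1]."""
    if a.size != b.size:
        raise ValueError("parent chromosomes must have equal length")
    c1, c2 = a.copy(), b.copy()
    if rng.random() < config.crossover_prob:
        cut = int(rng.integers(1, a.size))
        c1[cut:], c2[cut:] = b[cut:].copy(), a[cut:].copy()
    return c1, c2


def bitflip_mutate(bits: np.ndarray, config: GAConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Each bit flips independently with probability mutation_prob."""
    flips = rng.random(bits.size) < config.mutation_prob
    return (bits ^ flips.astype(np.uint8)).astype(np.uint8)


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def _assign_fronts(individuals: list[Individual]) -> list[list[int]]:
    fronts = fast_nondominated_sort([ind.objectives for ind in individuals])
    for r, front in enumerate(fronts, start=1):
        crowd = crowding_distance([individuals[i].objectives for i in front])
        for i, c in zip(front, crowd):
            individuals[i].rank = r
            individuals[i].crowding = float(c)
    return fronts


def _front_stats(generation: int, front: list[Individual]) -> GenerationStat:
    uniq: dict[bytes, tuple] = {}
    for ind in front:
        uniq.setdefault(ind.key, ind.objectives)
    arr = np.array(list(uniq.values()), dtype=float)
    return GenerationStat(
        generation=generation,
        front_size=len(uniq),
        mean_size=float(arr[:, 0].mean()),
        mean_separation=float(arr[:, 1].mean()),
        mean_relevance=float(arr[:, 2].mean()),
    )


def _unique_front(individuals: list[Individual]) -> list[Individual]:
    seen: set[bytes] = set()
    out = []
    for ind in individuals:
        if ind.rank == 1 and ind.key not in seen:
            seen.add(ind.key)
            out.append(ind)
    return out


def evolve(evaluate: Callable[[np.ndarray], tuple], k: int,
           config: GAConfig) -> GARunResult:
    """Run the generational loop until front-1 stagnation or the generation cap.

    ``evaluate`` maps a bit vector to the (size, separation, relevance)
    triple; it is typically a memoizing
    :class:`paretosig.objectives.ObjectiveEvaluator`.
    """
    rng = np.random.default_rng(config.seed)
    parents = [Individual(bits=b) for b in initialize_population(k, config, rng)]
    for ind in parents:
        ind.objectives = tuple(evaluate(ind.bits))
    _assign_fronts(parents)
    front_keys = frozenset(ind.key for ind in parents if ind.rank == 1)

    history = [_front_stats(0, _unique_front(parents))]
    stagnant = 0
    generation = 0
    n = config.population_size

    while generation < config.max_generations and stagnant < config.stagnation_generations:
        generation += 1
        offspring: list[Individual] = []
        while len(offspring) < n:
            p1 = tournament_select(parents, config, rng)
            p2 = tournament_select(parents, config, rng)
            c1, c2 = single_point_crossover(p1.bits, p2.bits, config, rng)
            for child in (c1, c2):
                child = bitflip_mutate(child, config, rng)
                child = repair_all_zero(child, rng)
                offspring.append(Individual(bits=child))
        offspring = offspring[:n]
        for ind in offspring:
            ind.objectives = tuple(evaluate(ind.bits))

        merged = parents + offspring
        fronts = fast_nondominated_sort([ind.objectives for ind in merged])
        survivors: list[Individual] = []
        for r, front in enumerate(fronts, start=1):
            members = [merged[i] for i in front]
            crowd = crowding_distance([m.objectives for m in members])
            for m, c in zip(members, crowd):
                m.rank = r
                m.crowding = float(c)
            if len(survivors) + len(members) <= n:
                survivors.extend(members)
            else:
                need = n - len(survivors)
                order = sorted(range(len(members)),
                               key=lambda i: (-crowd[i], front[i]))
                survivors.extend(members[i] for i in order[:need])
                break
        parents = survivors

        new_front_keys = frozenset(ind.key for ind in parents if ind.rank == 1)
        stagnant = stagnant + 1 if new_front_keys == front_keys else 0
        front_keys = new_front_keys
        history.append(_front_stats(generation, _unique_front(parents)))
        if generation % 50 == 0:
            h = history[-1]
            logger.info(
                "generation %d: front size %d, mean size %.2f, "
                "mean separation %.3f, mean relevance %.3f",
                generation, h.front_size, h.mean_size, h.mean_separation,
                h.mean_relevance,
            )

    terminated_by = "stagnation" if stagnant >= config.stagnation_generations \
        else "max_generations"
    return GARunResult(
        population=parents,
        front=_unique_front(parents),
        history=history,
        generations=generation,
        terminated_by=terminated_by,
    )
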