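"""Genetic-algorithm search over path orderings, and a simulated-annealing baseline.

One GA generation: a mating pool is built by ``s`` fitness tournaments on
random pairs, crossover exchanges whole path orderings between paired pool
members, mutation re-draws individual paths' intermediate permutations, and
elitism carries the top ``⌊p_E·s⌋`` members of the current population over
verbatim.  Every operator permutes intermediates only, so each chromosome
stays inside the feasible set throughout the run.

The SA baseline is a single-state Metropolis chain with a transposition move
(swap two intermediate positions in one path) and the logarithmic cooling
schedule ``T_k = c / log(k + 1)`` with cooling constant ``c = 10``.  The
move and schedule are a reconstruction of the classic annealing approach to
this search space, not a quotation of any particular implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    Chromosome,
    Compendium,
    GAConfig,
    Orderings,
    random_feasible_orderings,
    validate_orderings,
)
from .scoring import network_fitness

__all__ = [
    "Population",
    "RunResult",
    "SAConfig",
    "FitnessCache",
    "init_population",
    "tournament_select",
    "crossover",
    "mutate",
    "apply_elitism",
    "run_ga",
    "run_sa",
]


@dataclass
class Population:
    members: list[Chromosome]
    generation_index: int = 0

    @property
    def s(self) -> int:
        return len(self.members)

    def fitnesses(self) -> np.ndarray:
        return np.array([c.fitness for c in self.members], dtype=float)

    def best(self) -> Chromosome:
        return max(self.members, key=lambda c: c.fitness)


@dataclass
class RunResult:
    """Outcome of one search run.

    ``trace_best`` / ``trace_mean`` hold the per-generation best and mean
    fitness (index 0 = initial population); ``best_so_far_trace`` is the
    running maximum and ``best_so_far_orderings`` the matching orderings per
    generation, so path-recovery can be traced after the fact.
    """

    best_orderings: Orderings
    best_fitness: float
    trace_best: np.ndarray
    trace_mean: np.ndarray
    best_so_far_trace: np.ndarray
    best_so_far_orderings: list[Orderings] = field(repr=False, default_factory=list)


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing parameters; ``cooling_constant`` defaults to 10."""

    cooling_constant: float = 10.0
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cooling_constant <= 0:
            raise ValueError("cooling_constant must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


class FitnessCache:
    """Memoized self-estimated fitness, keyed on the orderings tuple.

    Elitism and converged populations re-present identical chromosomes; the
    cache makes those re-evaluations free.
    """

    def __init__(self, compendium: Compendium):
        self.compendium = compendium
        self._cache: dict[Orderings, float] = {}
        self.misses = 0

    def score(self, chromosome: Chromosome) -> float:
        if chromosome.fitness is None:
            f = self._cache.get(chromosome.orderings)
            if f is None:
                f = network_fitness(self.compendium, chromosome.orderings)
                self._cache[chromosome.orderings] = f
                self.misses += 1
            chromosome.fitness = f
        return chromosome.fitness

    def score_all(self, members: list[Chromosome]) -> None:
        for c in members:
            self.score(c)


def init_population(
    compendium: Compendium, config: GAConfig, rng: np.random.Generator,
    cache: FitnessCache | None = None,
) -> Population:
    """``s`` independent uniform draws from the feasible set, all scored."""
    cache = cache or FitnessCache(compendium)
    members = [
        Chromosome(random_feasible_orderings(compendium, rng)) for _ in range(config.s)
    ]
    cache.score_all(members)
    return Population(members, generation_index=0)


def tournament_select(population: Population, rng: np.random.Generator) -> list[Chromosome]:
    """``s`` tournaments on uniformly drawn distinct pairs; the fitter member of
    each pair is copied into the pool, ties broken uniformly at random."""
    s = population.s
    pool: list[Chromosome] = []
    for _ in range(s):
        i = int(rng.integers(s))
        j = int(rng.integers(s - 1))
        if j >= i:
            j += 1
        a, b = population.members[i], population.members[j]
        if a.fitness > b.fitness:
            win = a
        elif b.fitness > a.fitness:
            win = b
        else:
            win = a if rng.random() < 0.5 else b
        pool.append(win.copy())
    return pool


def crossover(
    pool: list[Chromosome], p_C: float, c_N: int, rng: np.random.Generator,
) -> list[Chromosome]:
    """Shuffle the pool, pair adjacent members, and with probability ``p_C``
    per pair exchange the orderings at ``c_N`` gene-set indices (the same
    indices in both parents, drawn without replacement)."""
    if len(pool) % 2:
        raise ValueError("crossover needs an even pool")
    m = len(pool[0].orderings)
    if c_N > m:
        raise ValueError(f"c_N={c_N} exceeds the number of gene sets m={m}")
    order = rng.permutation(len(pool))
    out: list[Chromosome] = []
    for t in range(0, len(pool), 2):
        a, b = pool[order[t]], pool[order[t + 1]]
        if rng.random() < p_C:
            idxs = rng.choice(m, size=c_N, replace=False)
            oa, ob = list(a.orderings), list(b.orderings)
            for i in idxs:
                oa[i], ob[i] = ob[i], oa[i]
            a = Chromosome(tuple(oa))
            b = Chromosome(tuple(ob))
        out.extend((a, b))
    return out


def _redraw_path(path: tuple[str, ...], rng: np.random.Generator) -> tuple[str, ...]:
    """Uniform re-draw of a path's intermediate arrangement (identity allowed)."""
    mid = list(path[1:-1])
    if len(mid) > 1:
        perm = rng.permutation(len(mid))
        mid = [mid[j] for j in perm]
    return (path[0],) + tuple(mid) + (path[-1],)


def mutate(
    pool: list[Chromosome], p_M: float, rng: np.random.Generator,
    scope: str = "per_path",
) -> list[Chromosome]:
    """Mutation by uniform re-permutation of a path's intermediates.

    ``per_path`` (default): every path of every chromosome mutates
    independently with probability ``p_M``.  ``per_chromosome``: each
    chromosome mutates with probability ``p_M``, re-drawing one uniformly
    chosen path.  The re-draw is uniform over all ``(L−2)!`` arrangements, so
    at ``L = 4`` the effective change rate is ``p_M/2``.
    """
    if not pool:
        return pool
    m = len(pool[0].orderings)
    out: list[Chromosome] = []
    if scope == "per_path":
        hits = rng.random((len(pool), m)) < p_M
        for c, row in zip(pool, hits):
            if row.any():
                paths = list(c.orderings)
                for i in np.nonzero(row)[0]:
                    paths[i] = _redraw_path(paths[i], rng)
                c = Chromosome(tuple(paths))
            out.append(c)
    elif scope == "per_chromosome":
        hits = rng.random(len(pool)) < p_M
        for c, hit in zip(pool, hits):
            if hit:
                i = int(rng.integers(m))
                paths = list(c.orderings)
                paths[i] = _redraw_path(paths[i], rng)
                c = Chromosome(tuple(paths))
            out.append(c)
    else:
        raise ValueError(f"unknown mutation scope {scope!r}")
    return out


def apply_elitism(
    population: Population, operated_pool: list[Chromosome], p_E: float,
    rng: np.random.Generator,
) -> Population:
    """Next generation: ``e = ⌊p_E·s⌋`` top-fitness members of the *current*
    population copied verbatim, the remaining ``s − e`` slots filled by a
    uniform random subset of the operated pool."""
    s = population.s
    e = math.floor(p_E * s)
    elites = sorted(population.members, key=lambda c: c.fitness, reverse=True)[:e]
    elites = [c.copy() for c in elites]
    keep = rng.choice(len(operated_pool), size=s - e, replace=False)
    survivors = [operated_pool[i] for i in keep]
    return Population(elites + survivors, generation_index=population.generation_index + 1)


def run_ga(
    compendium: Compendium,
    config: GAConfig,
    check_invariants: bool = False,
) -> RunResult:
    """Full GA run: init → [tournament → crossover → mutation → elitism] × J.

    Reproducible bit-for-bit from ``config.seed``.  With
    ``check_invariants=True`` every chromosome of every generation is
    validated against the compendium (feasibility closure) — useful in tests,
    off by default in the hot loop.
    """
    rng = np.random.default_rng(config.seed)
    cache = FitnessCache(compendium)
    pop = init_population(compendium, config, rng, cache)

    trace_best, trace_mean, trace_bsf = [], [], []
    bsf_orderings: list[Orderings] = []
    best = pop.best().copy()

    def record(p: Population) -> None:
        nonlocal best
        fits = p.fitnesses()
        gen_best = p.best()
        if gen_best.fitness > best.fitness:
            best = gen_best.copy()
        trace_best.append(float(fits.max()))
        trace_mean.append(float(fits.mean()))
        trace_bsf.append(best.fitness)
        bsf_orderings.append(best.orderings)
        if check_invariants:
            for c in p.members:
                validate_orderings(compendium, c.orderings)

    record(pop)
    for _ in range(config.J):
        pool = tournament_select(pop, rng)
        pool = crossover(pool, config.p_C, config.c_N, rng)
        pool = mutate(pool, config.p_M, rng, scope=config.mutation_scope)
        cache.score_all(pool)
        pop = apply_elitism(pop, pool, config.p_E, rng)
        record(pop)

    return RunResult(
        best_orderings=best.orderings,
        best_fitness=best.fitness,
        trace_best=np.array(trace_best),
        trace_mean=np.array(trace_mean),
        best_so_far_trace=np.array(trace_bsf),
        best_so_far_orderings=bsf_orderings,
    )


def run_sa(compendium: Compendium, config: SAConfig) -> RunResult:
    """Simulated-annealing baseline over the same feasible set.

    Starts from a uniform feasible draw; step ``k`` proposes swapping two
    intermediate positions in one uniformly chosen gene set of length ≥ 4 and
    accepts with probability ``min(1, exp(Δf / T_k))``, ``T_k = c/log(k+1)``.
    """
    movable = [i for i, gs in enumerate(compendium.gene_sets) if gs.length >= 4]
    if not movable:
        raise ValueError(
            "simulated annealing needs at least one gene set of length >= 4 "
            "(shorter sets have a unique ordering)"
        )
    rng = np.random.default_rng(config.seed)
    current = random_feasible_orderings(compendium, rng)
    f_cur = network_fitness(compendium, current)
    best, f_best = current, f_cur

    trace = [f_cur]
    trace_bsf = [f_best]
    bsf_orderings = [best]
    for k in range(1, config.iterations + 1):
        i = movable[int(rng.integers(len(movable)))]
        L = len(current[i])
        p = int(rng.integers(1, L - 1))
        q = int(rng.integers(1, L - 2))
        if q >= p:
            q += 1
        path = list(current[i])
        path[p], path[q] = path[q], path[p]
        proposal = current[:i] + (tuple(path),) + current[i + 1:]
        f_prop = network_fitness(compendium, proposal)
        delta = f_prop - f_cur
        temp = config.cooling_constant / math.log(k + 1)
        if delta >= 0 or rng.random() < math.exp(delta / temp):
            current, f_cur = proposal, f_prop
            if f_cur > f_best:
                best, f_best = current, f_cur
        trace.append(f_cur)
        trace_bsf.append(f_best)
        bsf_orderings.append(best)

    trace_arr = np.array(trace)
    return RunResult(
        best_orderings=best,
        best_fitness=f_best,
        trace_best=trace_arr,
        trace_mean=trace_arr.copy(),
        best_so_far_trace=np.array(trace_bsf),
        best_so_far_orderings=bsf_orderings,
    )
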