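"""Elitist genetic algorithm over combinatorial nutrient environments.

The evolutionary loop: a population of P candidate environments is evaluated
and ranked; the top σ are carried over as parents; the remaining P−σ
offspring are random assortments drawn from the pooled parent nutrients
(crossover, per-offspring probability pC, otherwise a fresh random
environment); every nutrient slot of every environment except the top-ranked
one is then mutated with probability pM into a nutrient not currently in that
environment.  The loop stops when three convergence criteria hold jointly —
population internal consistency, best-vs-best-ever stagnation, and no
statistically significant generation-over-generation improvement for a run of
generations (one-tailed Welch t-test) — or after G generations.

Evaluations are memoised per unique environment, so the history reports the
number of unique (in silico or wet-lab) experiments actually required.  A
seed-matched random-search baseline with identical bookkeeping is provided
for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .env_space import Environment, EnvironmentSpace, canonical_sort_key, random_environment
from .objectives import Objective
from .phenotype_metrics import PhenotypeSummary

__all__ = [
    "GAConfig",
    "ConvergenceCriteria",
    "EvaluatedMember",
    "EvaluatedPopulation",
    "GAHistory",
    "initialize_population",
    "select_parents",
    "make_offspring",
    "mutate",
    "check_convergence",
    "run_ga",
    "run_random_search",
]

#: Fitness assigned to an environment whose evaluation failed.
FAILURE_FITNESS = -1e18

Evaluator = Callable[[Environment], PhenotypeSummary]


@dataclass(frozen=True)
class GAConfig:
    """Search parameters.

    Defaults follow the operating point used throughout: an experimentally
    tractable population of P=10, σ=2 parents, crossover probability 0.9 and
    per-nutrient mutation probability 0.35 (kept under 0.5 so mutation cannot
    randomise solutions away faster than selection concentrates them).
    """

    N: int  # max nutrients per environment
    P: int = 10
    sigma: int = 2
    pC: float = 0.9
    pM: float = 0.35
    G: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if not 1 <= self.sigma <= self.P:
            raise ValueError(f"sigma must satisfy 1 <= sigma <= P, got {self.sigma}")
        if not 0 <= self.pC <= 1:
            raise ValueError("pC must be in [0, 1]")
        if not 0 <= self.pM < 0.5:
            raise ValueError("pM must be in [0, 0.5)")
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if self.N < 1:
            raise ValueError("N must be >= 1")


@dataclass(frozen=True)
class ConvergenceCriteria:
    """Thresholds for the three-part convergence test."""

    rel_gap: float = 0.10
    best_tol: float = 0.01
    stall_generations: int = 10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if min(self.rel_gap, self.best_tol, self.alpha) <= 0:
            raise ValueError("rel_gap, best_tol and alpha must be > 0")
        if self.stall_generations < 1:
            raise ValueError("stall_generations must be >= 1")


@dataclass(frozen=True)
class EvaluatedMember:
    env: Environment
    fitness: float  # always-maximize scale
    raw: float  # objective value on its natural scale


@dataclass(frozen=True)
class EvaluatedPopulation:
    """One generation's members, ranked best-first (ties broken canonically)."""

    members: tuple[EvaluatedMember, ...]

    @property
    def fitnesses(self) -> np.ndarray:
        return np.array([m.fitness for m in self.members])

    @property
    def best(self) -> EvaluatedMember:
        return self.members[0]

    def environments(self) -> list[Environment]:
        return [m.env for m in self.members]


@dataclass
class GAHistory:
    """Full record of one run: per-generation populations and bookkeeping."""

    generations: list[EvaluatedPopulation] = field(default_factory=list)
    best_so_far: list[float] = field(default_factory=list)
    best_env_so_far: list[Environment] = field(default_factory=list)
    unique_evaluations: int = 0
    total_evaluations: int = 0
    converged: bool = False
    criterion_flags: dict[str, bool] = field(default_factory=dict)
    terminated: str = ""
    failures: list[tuple[Environment, str]] = field(default_factory=list)

    @property
    def n_generations(self) -> int:
        return len(self.generations)

    @property
    def best_fitness(self) -> float:
        return self.best_so_far[-1]

    @property
    def best_environment(self) -> Environment:
        return self.best_env_so_far[-1]

    def best_per_generation(self) -> np.ndarray:
        return np.array([g.best.fitness for g in self.generations])


def initialize_population(
    space: EnvironmentSpace, P: int, rng: np.random.Generator
) -> list[Environment]:
    """P random admissible non-empty environments (duplicates permitted)."""
    if P < 1:
        raise ValueError("P must be >= 1")
    return [random_environment(space, rng) for _ in range(P)]


def rank_population(
    evaluated: Sequence[EvaluatedMember], space: EnvironmentSpace
) -> EvaluatedPopulation:
    """Sort best-first by fitness; ties broken by canonical environment order."""
    key = lambda m: (-m.fitness, canonical_sort_key(m.env, space.pool))
    return EvaluatedPopulation(tuple(sorted(evaluated, key=key)))


def select_parents(pop: EvaluatedPopulation, sigma: int) -> list[Environment]:
    """The σ best-ranked environments, order preserved."""
    if sigma > len(pop.members):
        raise ValueError("sigma exceeds population size")
    return [m.env for m in pop.members[:sigma]]


def make_offspring(
    parents: Sequence[Environment],
    P: int,
    sigma: int,
    pC: float,
    N: int,
    space: EnvironmentSpace,
    rng: np.random.Generator,
) -> list[Environment]:
    """P−σ offspring: with probability pC a random assortment (size uniform in
    1..N, capped at availability) drawn without replacement from the pooled
    parent nutrients; otherwise a fresh random environment from the pool."""
    if not parents:
        raise ValueError("parents must be non-empty")
    pool_union: set[str] = set()
    for p in parents:
        pool_union.update(p.nutrient_ids)
    union = sorted(pool_union, key=space.pool.index_of)
    offspring: list[Environment] = []
    for _ in range(P - sigma):
        if rng.random() < pC:
            size = min(int(rng.integers(1, N + 1)), len(union))
            idx = rng.choice(len(union), size=size, replace=False)
            offspring.append(Environment(frozenset(union[i] for i in idx)))
        else:
            offspring.append(random_environment(space, rng))
    return offspring


def mutate_environment(
    env: Environment, pM: float, space: EnvironmentSpace, rng: np.random.Generator
) -> Environment:
    """Each nutrient independently replaced with probability pM by a uniform
    choice among nutrients not currently in the environment."""
    current = set(env.nutrient_ids)
    for nid in sorted(env.nutrient_ids, key=space.pool.index_of):
        if rng.random() < pM:
            candidates = [p for p in space.pool.ids if p not in current]
            if not candidates:
                continue  # pool exhausted: slot left unchanged
            new = candidates[int(rng.integers(len(candidates)))]
            current.remove(nid)
            current.add(new)
    return Environment(frozenset(current))


def mutate(
    population: Sequence[Environment],
    pM: float,
    space: EnvironmentSpace,
    rng: np.random.Generator,
) -> list[Environment]:
    """Mutate every environment except the top-ranked one (index 0)."""
    out = [population[0]]
    for env in population[1:]:
        out.append(mutate_environment(env, pM, space, rng))
    return out


def _shifted(values: np.ndarray) -> np.ndarray:
    """Shift scores by |min| + 1 so ratios are well defined on any sign."""
    return values + abs(values.min()) + 1.0


def _significant_increase(
    current: np.ndarray, previous: np.ndarray, alpha: float
) -> bool:
    """One-tailed two-sample Welch t-test: did fitness significantly increase?

    Direct computation (equivalent to scipy's ttest_ind with equal_var=False,
    alternative='greater'); zero variance on both sides, where the statistic
    is undefined, counts as no increase.
    """
    n1, n2 = current.size, previous.size
    if min(n1, n2) < 2:
        return False
    v1 = current.var(ddof=1)
    v2 = previous.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        # degenerate: both samples constant — any strict mean increase is real
        return current.mean() > previous.mean()
    t = (current.mean() - previous.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = float(stats.t.sf(t, df))
    return p < alpha


def check_convergence(
    history: GAHistory, criteria: ConvergenceCriteria
) -> tuple[bool, dict[str, bool]]:
    """The three-criterion convergence test on a run in progress.

    1. internal consistency: (best − mean)/mean < rel_gap within the current
       generation; 2. stagnation: |best_ever − best_current|/|best_ever| <
       best_tol; 3. no improvement: no significant generation-over-generation
       fitness increase (one-tailed Welch t-test at level alpha) for each of
       the last ``stall_generations`` generations.  Scores are shifted by
       |min|+1 wherever a denominator would be zero or negative.
    """
    if not history.generations:
        raise ValueError("need at least one completed generation")
    last = history.generations[-1].fitnesses

    scores = last if last.mean() > 0 else _shifted(last)
    flag1 = bool((scores.max() - scores.mean()) / scores.mean() < criteria.rel_gap)

    best_ever = history.best_so_far[-1]
    best_cur = float(last.max())
    pair = np.array([best_ever, best_cur])
    if best_ever <= 0:
        pair = _shifted(pair)
    flag2 = bool(abs(pair[0] - pair[1]) / abs(pair[0]) < criteria.best_tol)

    gens = history.generations
    if len(gens) >= criteria.stall_generations + 1:
        flag3 = not any(
            _significant_increase(
                gens[-k].fitnesses, gens[-k - 1].fitnesses, criteria.alpha
            )
            for k in range(1, criteria.stall_generations + 1)
        )
    else:
        flag3 = False

    flags = {
        "internal_consistency": flag1,
        "reached_maximum": flag2,
        "no_improvement": flag3,
    }
    return all(flags.values()), flags


class _MemoisedEvaluator:
    """Wraps an evaluator with a memo keyed on the environment's id set."""

    def __init__(self, evaluator: Evaluator, objective: Objective, history: GAHistory):
        self._evaluator = evaluator
        self._objective = objective
        self._history = history
        self._memo: dict[frozenset[str], tuple[float, float]] = {}

    def __call__(self, env: Environment) -> tuple[float, float]:
        self._history.total_evaluations += 1
        key = env.nutrient_ids
        if key in self._memo:
            return self._memo[key]
        self._history.unique_evaluations += 1
        try:
            summary = self._evaluator(env)
            fitness = self._objective.score(summary)
            raw = self._objective.raw(summary)
        except Exception as exc:  # evaluator failure: worst fitness, run continues
            self._history.failures.append((env, repr(exc)))
            fitness, raw = FAILURE_FITNESS, float("nan")
        self._memo[key] = (fitness, raw)
        return fitness, raw


def _record_generation(
    history: GAHistory,
    population: Sequence[Environment],
    memo: _MemoisedEvaluator,
    space: EnvironmentSpace,
) -> EvaluatedPopulation:
    members = []
    for env in population:
        fitness, raw = memo(env)
        members.append(EvaluatedMember(env, fitness, raw))
    ranked = rank_population(members, space)
    best = ranked.best
    if not history.best_so_far or best.fitness > history.best_so_far[-1]:
        history.best_so_far.append(best.fitness)
        history.best_env_so_far.append(best.env)
    else:
        history.best_so_far.append(history.best_so_far[-1])
        history.best_env_so_far.append(history.best_env_so_far[-1])
    history.generations.append(ranked)
    return ranked


def run_ga(
    space: EnvironmentSpace,
    evaluator: Evaluator,
    objective: Objective,
    config: GAConfig,
    criteria: ConvergenceCriteria | None = None,
) -> GAHistory:
    """Run the full evolutionary loop; reproducible under a fixed seed with a
    deterministic evaluator."""
    criteria = criteria or ConvergenceCriteria()
    rng = np.random.default_rng(config.seed)
    history = GAHistory()
    memo = _MemoisedEvaluator(evaluator, objective, history)

    population = initialize_population(space, config.P, rng)
    for _ in range(config.G):
        ranked = _record_generation(history, population, memo, space)
        converged, flags = check_convergence(history, criteria)
        history.criterion_flags = flags
        if converged:
            history.converged = True
            history.terminated = "converged"
            break
        parents = select_parents(ranked, config.sigma)
        offspring = make_offspring(
            parents, config.P, config.sigma, config.pC, config.N, space, rng
        )
        population = mutate(parents + offspring, config.pM, space, rng)
    else:
        history.terminated = "max_generations"
    return history


def run_random_search(
    space: EnvironmentSpace,
    evaluator: Evaluator,
    objective: Objective,
    config: GAConfig,
    criteria: ConvergenceCriteria | None = None,
) -> GAHistory:
    """Fitness-blind baseline with identical bookkeeping to :func:`run_ga`.

    Each new generation re-samples σ environments uniformly (with
    replacement) from everything proposed so far and fills the remaining P−σ
    slots with fresh random environments — novelty enters where crossover and
    mutation would act in the GA.  Runs for the full G generations (no
    fitness-based stopping, keeping generation counts comparable)."""
    criteria = criteria or ConvergenceCriteria()
    rng = np.random.default_rng(config.seed)
    history = GAHistory()
    memo = _MemoisedEvaluator(evaluator, objective, history)

    proposed: list[Environment] = []
    population = initialize_population(space, config.P, rng)
    for _ in range(config.G):
        proposed.extend(population)
        _record_generation(history, population, memo, space)
        _, history.criterion_flags = check_convergence(history, criteria)
        population = [
            proposed[int(rng.integers(len(proposed)))] for _ in range(config.sigma)
        ] + [random_environment(space, rng) for _ in range(config.P - config.sigma)]
    history.terminated = "max_generations"
    return history
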