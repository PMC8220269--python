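"""Search-performance metrics against an exhaustively enumerated reference.

On an enumerable environment space the full fitness distribution is known, so
a run can be scored by (i) G99 — the generation at which its best fitness
first strictly exceeds the 99th percentile of the reference distribution —
and (ii) Prend — the percentile rank of the best-ever fitness at the final
generation.  The combined performance score is S = (1 − G99~) + Prend~ with
both terms min–max normalised to [0, 1], so S ranges from 0 (worst) to 2
(best).  A [pC, pM] grid search averages S over many seeded runs per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community_sim import Mapping as EnvMapping
from .env_space import EnvironmentSpace
from .ga_engine import ConvergenceCriteria, Evaluator, GAConfig, GAHistory, run_ga
from .objectives import Objective

__all__ = [
    "ReferenceDistribution",
    "RunMetrics",
    "GridSearchResult",
    "percentile_threshold",
    "percentile_rank",
    "compute_metrics",
    "compute_S",
    "grid_search",
    "aggregate_runs",
    "average_best_pairs",
    "derive_seeds",
]

DEFAULT_PC_GRID = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10))
DEFAULT_PM_GRID = tuple(np.round(np.arange(0.0, 0.45 + 1e-9, 0.05), 10))


@dataclass(frozen=True)
class ReferenceDistribution:
    """Fitness of every environment in an enumerated space, fixed objective."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("reference distribution must be non-empty")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_mapping(cls, mapping: EnvMapping, objective: Objective) -> "ReferenceDistribution":
        return cls(np.array([objective.score(s) for s in mapping.summaries()]))

    @property
    def maximum(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class RunMetrics:
    """G99, Prend and (once normalised against a grid) S for one run."""

    g99: int | None  # generations to first strictly exceed the 99th pct; None = never
    prend: float  # percentile of best-ever fitness at the final generation
    s: float | None = None


def percentile_threshold(ref: ReferenceDistribution, q: float) -> float:
    """The q-th percentile of the reference values (linear interpolation)."""
    if not 0 <= q <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {q}")
    return float(np.percentile(ref.values, q, method="linear"))


def percentile_rank(ref: ReferenceDistribution, x: float, kind: str = "weak") -> float:
    """Percentile rank of x within the reference values.

    ``weak`` (default): fraction of values <= x — the enumerated maximum
    ranks at exactly 100.  ``strict``: fraction strictly below.  ``midrank``:
    strictly below plus half the ties.
    """
    v = ref.values
    below = float((v < x).sum())
    ties = float((v == x).sum())
    n = v.size
    if kind == "weak":
        return 100.0 * (below + ties) / n
    if kind == "strict":
        return 100.0 * below / n
    if kind == "midrank":
        return 100.0 * (below + 0.5 * ties) / n
    raise ValueError(f"unknown percentile-rank kind {kind!r}")


def compute_metrics(
    history: GAHistory,
    ref: ReferenceDistribution,
    *,
    q: float = 99.0,
    rank_kind: str = "weak",
) -> RunMetrics:
    """G99 and Prend for one finished run against its reference distribution."""
    threshold = percentile_threshold(ref, q)
    best_per_gen = history.best_per_generation()
    exceeding = np.flatnonzero(best_per_gen > threshold)
    g99 = int(exceeding[0]) + 1 if exceeding.size else None
    prend = percentile_rank(ref, history.best_fitness, kind=rank_kind)
    return RunMetrics(g99=g99, prend=prend)


def compute_S(g99_norm: float, prend_norm: float) -> float:
    """Performance score S = (1 − G99~) + Prend~, both terms in [0, 1]."""
    if not 0 <= g99_norm <= 1:
        raise ValueError(f"g99_norm must be in [0, 1], got {g99_norm}")
    if not 0 <= prend_norm <= 1:
        raise ValueError(f"prend_norm must be in [0, 1], got {prend_norm}")
    return (1.0 - g99_norm) + prend_norm


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds (< 2³¹) from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def aggregate_runs(metrics: Sequence[RunMetrics]) -> dict[str, float | int | None]:
    """Mean and s.e.m. (sd/√n) of G99, Prend and S over finite entries.

    Runs that never crossed the threshold are excluded from the G99 mean and
    reported separately as ``n_never``.
    """

    def mean_sem(values: list[float]) -> tuple[float | None, float | None]:
        if not values:
            return None, None
        arr = np.asarray(values, dtype=float)
        mean = float(arr.mean())
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size >= 2 else None
        return mean, sem

    g99s = [float(m.g99) for m in metrics if m.g99 is not None]
    prends = [m.prend for m in metrics]
    ss = [m.s for m in metrics if m.s is not None]
    mean_g99, sem_g99 = mean_sem(g99s)
    mean_prend, sem_prend = mean_sem(prends)
    mean_s, sem_s = mean_sem(ss)
    return {
        "n_runs": len(metrics),
        "n_never": sum(1 for m in metrics if m.g99 is None),
        "mean_g99": mean_g99,
        "sem_g99": sem_g99,
        "mean_prend": mean_prend,
        "sem_prend": sem_prend,
        "mean_s": mean_s,
        "sem_s": sem_s,
    }


@dataclass
class GridSearchResult:
    """Mean S per (pC, pM) cell and objective, plus best pairs."""

    table: pd.DataFrame  # columns pC, pM, objective, mean_S, sem_S, mean_G99, mean_Prend, n_never
    best_per_objective: dict[str, tuple[float, float]]
    averaged_best: tuple[float, float]


def average_best_pairs(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Component-wise mean of per-objective best (pC, pM) pairs."""
    arr = np.asarray(pairs, dtype=float)
    return (float(arr[:, 0].mean()), float(arr[:, 1].mean()))


def grid_search(
    space: EnvironmentSpace,
    evaluator: Evaluator,
    objectives: Mapping[str, Objective],
    references: Mapping[str, ReferenceDistribution],
    *,
    base_config: GAConfig,
    pC_grid: Sequence[float] = DEFAULT_PC_GRID,
    pM_grid: Sequence[float] = DEFAULT_PM_GRID,
    n_seeds: int = 50,
    criteria: ConvergenceCriteria | None = None,
    base_seed: int = 0,
) -> GridSearchResult:
    """Exhaustive [pC, pM] grid: per cell and objective, run the GA over the
    shared seed list and average the performance score S.

    G99~ and Prend~ are min–max normalised per objective across every run in
    the grid; runs that never crossed the 99th percentile have G99 mapped to
    the largest observed (or G) before normalisation.  The best cell per
    objective maximises mean S (ties to the lexicographically smallest pair);
    the across-objective operating point averages the best pairs.
    """
    missing = set(objectives) - set(references)
    if missing:
        raise ValueError(f"no reference distribution for objectives: {sorted(missing)}")
    seeds = derive_seeds(base_seed, n_seeds)
    cells = [(float(pc), float(pm)) for pc in pC_grid for pm in pM_grid]

    raw: dict[str, dict[tuple[float, float], list[RunMetrics]]] = {
        name: {} for name in objectives
    }
    for name, objective in objectives.items():
        ref = references[name]
        for pc, pm in cells:
            runs = []
            for seed in seeds:
                cfg = replace(base_config, pC=pc, pM=pm, seed=seed)
                history = run_ga(space, evaluator, objective, cfg, criteria)
                runs.append(compute_metrics(history, ref))
            raw[name][(pc, pm)] = runs

    rows = []
    best_per_objective: dict[str, tuple[float, float]] = {}
    for name in objectives:
        all_runs = [m for cell in raw[name].values() for m in cell]
        finite_g99 = [m.g99 for m in all_runs if m.g99 is not None]
        never_value = float(max(finite_g99)) if finite_g99 else float(base_config.G)
        g99_all = np.array(
            [float(m.g99) if m.g99 is not None else never_value for m in all_runs]
        )
        prend_all = np.array([m.prend for m in all_runs])
        g99_norm = _minmax(g99_all)
        prend_norm = _minmax(prend_all)
        s_all = (1.0 - g99_norm) + prend_norm

        i = 0
        cell_mean_s: dict[tuple[float, float], float] = {}
        for pc, pm in cells:
            runs = raw[name][(pc, pm)]
            k = len(runs)
            s_cell = s_all[i : i + k]
            scored = [replace(m, s=float(s)) for m, s in zip(runs, s_cell)]
            i += k
            agg = aggregate_runs(scored)
            cell_mean_s[(pc, pm)] = agg["mean_s"]
            rows.append(
                {
                    "pC": pc,
                    "pM": pm,
                    "objective": name,
                    "mean_S": agg["mean_s"],
                    "sem_S": agg["sem_s"],
                    "mean_G99": agg["mean_g99"],
                    "mean_Prend": agg["mean_prend"],
                    "n_never": agg["n_never"],
                }
            )
        best_per_objective[name] = min(
            cell_mean_s, key=lambda cell: (-cell_mean_s[cell], cell)
        )

    table = pd.DataFrame(rows)
    averaged = average_best_pairs(list(best_per_objective.values()))
    return GridSearchResult(
        table=table, best_per_objective=best_per_objective, averaged_best=averaged
    )
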