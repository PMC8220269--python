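"""Shared helpers for constructing synthetic GA histories in tests."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from envdesign.env_space import Environment
from envdesign.fixture import fixture_pool, fixture_space
from envdesign.ga_engine import EvaluatedMember, EvaluatedPopulation, GAHistory


def history_from_fitness(per_generation: Sequence[Sequence[float]]) -> GAHistory:
    """Build a GAHistory from raw per-generation fitness lists.

    Members within each generation get distinct single-nutrient dummy
    environments; ranking and the best-so-far trace are derived as the engine
    would derive them.
    """
    ids = fixture_pool().ids
    history = GAHistory()
    best = -np.inf
    best_env = None
    for fits in per_generation:
        members = tuple(
            EvaluatedMember(Environment.from_ids([ids[i % len(ids)]]), float(f), float(f))
            for i, f in enumerate(sorted(fits, reverse=True))
        )
        pop = EvaluatedPopulation(members)
        if pop.best.fitness > best:
            best = pop.best.fitness
            best_env = pop.best.env
        history.generations.append(pop)
        history.best_so_far.append(best)
        history.best_env_so_far.append(best_env)
    return history
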