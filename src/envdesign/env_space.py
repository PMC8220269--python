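"""Combinatorial nutrient environments.

An *environment* is the set of limiting carbon sources added to a fixed,
non-limiting base medium.  The space of candidate environments is the set of
all nutrient subsets of bounded size drawn from a finite pool; this module
represents, counts, enumerates and samples those subsets, and converts a
subset into a concrete medium composition (mmol per nutrient).

The combinatorics are closed-form binomial sums — counting never enumerates —
and enumeration is refused above an explicit cap so that very large spaces
(hundreds of thousands of subsets) are only ever searched, not materialised.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "Nutrient",
    "NutrientPool",
    "EnvironmentSpace",
    "Environment",
    "MediumSpec",
    "count_environments",
    "enumerate_environments",
    "random_environment",
    "build_medium",
    "canonical_sort_key",
]

SizeRule = Literal["up_to", "exact"]


@dataclass(frozen=True)
class Nutrient:
    """A carbon source: identifier, display name, carbon atoms per molecule."""

    id: str
    name: str
    carbon_atoms: int

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("nutrient id must be non-empty")
        if self.carbon_atoms < 1:
            raise ValueError(
                f"nutrient {self.id!r}: carbon_atoms must be >= 1, got {self.carbon_atoms}"
            )


@dataclass(frozen=True)
class NutrientPool:
    """An ordered collection of nutrients; order defines canonical indexing."""

    nutrients: tuple[Nutrient, ...]

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nutrients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate nutrient ids in pool: {dupes}")
        object.__setattr__(self, "_index", {n.id: i for i, n in enumerate(self.nutrients)})

    @classmethod
    def from_nutrients(cls, nutrients: Sequence[Nutrient]) -> "NutrientPool":
        return cls(tuple(nutrients))

    def __len__(self) -> int:
        return len(self.nutrients)

    def __iter__(self) -> Iterator[Nutrient]:
        return iter(self.nutrients)

    def __contains__(self, nutrient_id: str) -> bool:
        return nutrient_id in self._index  # type: ignore[attr-defined]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(n.id for n in self.nutrients)

    def index_of(self, nutrient_id: str) -> int:
        try:
            return self._index[nutrient_id]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"nutrient {nutrient_id!r} not in pool") from None

    def carbon_of(self, nutrient_id: str) -> int:
        return self.nutrients[self.index_of(nutrient_id)].carbon_atoms

    def carbon_atoms(self) -> dict[str, int]:
        """Mapping nutrient id -> carbon atoms per molecule."""
        return {n.id: n.carbon_atoms for n in self.nutrients}


@dataclass(frozen=True)
class Environment:
    """A duplicate-free set of nutrient ids; the GA's individual solution.

    Two environments are equal iff their id sets are equal; ordering of the
    ids never matters.  ``env_id`` is a stable content hash usable as a key
    in mapping files.
    """

    nutrient_ids: frozenset[str]

    @classmethod
    def from_ids(cls, ids: Sequence[str] | frozenset[str]) -> "Environment":
        return cls(frozenset(ids))

    def __len__(self) -> int:
        return len(self.nutrient_ids)

    def __contains__(self, nutrient_id: str) -> bool:
        return nutrient_id in self.nutrient_ids

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.nutrient_ids))

    @property
    def sorted_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.nutrient_ids))

    @property
    def env_id(self) -> str:
        """Stable 12-hex-digit hash of the sorted id set."""
        key = ";".join(self.sorted_ids)
        return hashlib.sha1(key.encode("utf-8")).hexdigest()[:12]

    def label(self) -> str:
        """Human-readable semicolon-joined id list ('' for the empty set)."""
        return ";".join(self.sorted_ids)


EMPTY_ENVIRONMENT = Environment(frozenset())


@dataclass(frozen=True)
class EnvironmentSpace:
    """All admissible environments over a pool: subsets of bounded size.

    ``size_rule='up_to'`` admits sizes 1..N (plus the empty set when
    ``include_empty``); ``size_rule='exact'`` admits only size N.
    """

    pool: NutrientPool
    max_nutrients: int
    include_empty: bool = False
    size_rule: SizeRule = "up_to"

    def __post_init__(self) -> None:
        if not 1 <= self.max_nutrients <= len(self.pool):
            raise ValueError(
                f"max_nutrients must be in [1, {len(self.pool)}], got {self.max_nutrients}"
            )
        if self.size_rule not in ("up_to", "exact"):
            raise ValueError(f"unknown size_rule {self.size_rule!r}")

    def admissible_sizes(self) -> range:
        if self.size_rule == "exact":
            return range(self.max_nutrients, self.max_nutrients + 1)
        lo = 0 if self.include_empty else 1
        return range(lo, self.max_nutrients + 1)

    def is_admissible(self, env: Environment) -> bool:
        return len(env) in self.admissible_sizes() and all(
            i in self.pool for i in env.nutrient_ids
        )

    def count(self) -> int:
        return count_environments(
            len(self.pool),
            self.max_nutrients,
            size_rule=self.size_rule,
            include_empty=self.include_empty,
        )


@dataclass(frozen=True)
class MediumSpec:
    """How an environment becomes mmol amounts.

    Default mode splits a fixed total carbon budget equimolarly: all nutrients
    at one molar amount x such that x · Σ carbon_atoms equals
    ``total_carbon_concentration`` (mM C) × ``volume`` (µl), i.e. 0.02 mmol C
    at the defaults (50 mM C in 400 µl).  When
    ``per_nutrient_amount_override`` is set, every nutrient is instead
    supplied at that fixed amount (mmol) regardless of carbon content.
    """

    total_carbon_concentration: float = 50.0  # mM carbon
    volume: float = 400.0  # microlitres
    per_nutrient_amount_override: float | None = None

    def __post_init__(self) -> None:
        if self.total_carbon_concentration <= 0:
            raise ValueError("total_carbon_concentration must be > 0")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        if (
            self.per_nutrient_amount_override is not None
            and self.per_nutrient_amount_override <= 0
        ):
            raise ValueError("per_nutrient_amount_override must be > 0 when set")

    @property
    def volume_litres(self) -> float:
        return self.volume * 1e-6

    @property
    def total_carbon_mmol(self) -> float:
        """Total carbon budget in mmol C (concentration × volume)."""
        return self.total_carbon_concentration * self.volume_litres


def count_environments(
    pool_size: int,
    k: int,
    *,
    size_rule: SizeRule = "up_to",
    include_empty: bool = False,
) -> int:
    """Number of admissible nutrient subsets, by closed-form binomial sums.

    ``up_to``: Σ_{j=1..k} C(n, j), plus 1 for the empty subset when
    ``include_empty``.  ``exact``: C(n, k).  Never enumerates.
    """
    if k < 0:
        raise ValueError(f"subset size must be >= 0, got {k}")
    if k > pool_size:
        raise ValueError(f"subset size {k} exceeds pool size {pool_size}")
    if size_rule == "exact":
        return comb(pool_size, k)
    if size_rule == "up_to":
        total = sum(comb(pool_size, j) for j in range(1, k + 1))
        return total + (1 if include_empty else 0)
    raise ValueError(f"unknown size_rule {size_rule!r}")


def enumerate_environments(
    space: EnvironmentSpace, cap: int = 100_000
) -> list[Environment]:
    """All environments of a space in canonical order (size, then lexicographic
    on canonical pool indices).  Refuses if the count exceeds ``cap``."""
    n = space.count()
    if n > cap:
        raise ValueError(
            f"space contains {n} environments, above the enumeration cap of {cap}; "
            "raise the cap explicitly or use on-demand evaluation instead"
        )
    ids = space.pool.ids
    out: list[Environment] = []
    for size in space.admissible_sizes():
        for combo in combinations(range(len(ids)), size):
            out.append(Environment(frozenset(ids[i] for i in combo)))
    assert len(out) == n
    return out


def random_environment(space: EnvironmentSpace, rng: np.random.Generator) -> Environment:
    """A random admissible non-empty environment.

    Subset size is uniform over the admissible non-empty sizes, then a uniform
    subset of that size — so small and large environments are equally likely,
    matching initial populations with a varying number of limiting nutrients.
    """
    if space.size_rule == "exact":
        size = space.max_nutrients
    else:
        size = int(rng.integers(1, space.max_nutrients + 1))
    idx = rng.choice(len(space.pool), size=size, replace=False)
    ids = space.pool.ids
    return Environment(frozenset(ids[i] for i in idx))


def canonical_sort_key(env: Environment, pool: NutrientPool) -> tuple:
    """Deterministic ordering key: subset size, then canonical pool indices."""
    idx = tuple(sorted(pool.index_of(i) for i in env.nutrient_ids))
    return (len(idx), idx)


def build_medium(
    env: Environment, spec: MediumSpec, pool: NutrientPool
) -> dict[str, float]:
    """Per-nutrient amounts (mmol) for an environment.

    Default mode: equimolar split of the total carbon budget; override mode:
    each nutrient at the fixed override amount.  The empty environment yields
    an empty dict (base medium only).
    """
    for nid in env.nutrient_ids:
        if nid not in pool:
            raise KeyError(f"environment nutrient {nid!r} not in pool")
    if len(env) == 0:
        return {}
    if spec.per_nutrient_amount_override is not None:
        return {nid: spec.per_nutrient_amount_override for nid in env.sorted_ids}
    total_atoms = sum(pool.carbon_of(nid) for nid in env.nutrient_ids)
    x = spec.total_carbon_mmol / total_atoms
    return {nid: x for nid in env.sorted_ids}
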