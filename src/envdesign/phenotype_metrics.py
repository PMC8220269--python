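"""Community-level summary statistics consumed by the objective functions.

All metrics are pure functions of simulator (or experimental) output: relative
abundances, Shannon entropy in bits (the measure of taxonomic balance),
species richness, and metabolic-exchange accounting.  One *exchange* is the
transfer of a unique metabolite from one organism to another — the secretion
of metabolite m by organism A and its absorption by organism B — so the
number of exchanges is the number of distinct (donor, receiver, metabolite)
triples, with amounts and repeat transfers collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ExchangeRecord",
    "PhenotypeSummary",
    "relative_abundances",
    "shannon_entropy",
    "species_richness",
    "count_exchanges",
    "max_possible_exchanges",
    "flux_to_organism",
    "secretion_total",
]


@dataclass(frozen=True)
class ExchangeRecord:
    """Cumulative transfer of one metabolite from a donor to a receiver."""

    donor: str
    receiver: str
    metabolite: str
    amount: float  # mmol, > 0

    def __post_init__(self) -> None:
        if self.donor == self.receiver:
            raise ValueError(f"exchange donor and receiver coincide: {self.donor!r}")
        if not self.amount > 0:
            raise ValueError(f"exchange amount must be > 0, got {self.amount}")


@dataclass(frozen=True)
class PhenotypeSummary:
    """Everything the objective families need to score one environment."""

    organism_ids: tuple[str, ...]
    final_biomass: tuple[float, ...]  # gDW per organism
    abundances: tuple[float, ...]  # relative abundances, sum to 1 (or all 0)
    richness: int
    entropy: float  # bits
    exchanges: tuple[ExchangeRecord, ...]
    secretion_totals: dict[str, float] = field(default_factory=dict)  # metabolite -> mmol
    flux_to: dict[str, float] = field(default_factory=dict)  # organism -> absorbed mmol

    @property
    def n_exchanges(self) -> int:
        return count_exchanges(self.exchanges)

    def abundance_of(self, organism_id: str) -> float:
        try:
            return self.abundances[self.organism_ids.index(organism_id)]
        except ValueError:
            raise KeyError(f"unknown organism {organism_id!r}") from None


def relative_abundances(final_biomass: Sequence[float] | np.ndarray) -> np.ndarray:
    """Each organism's share of total final biomass.

    An all-zero vector (extinct community) maps to the reserved all-zero
    abundance vector rather than dividing by zero.
    """
    b = np.asarray(final_biomass, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass values must be >= 0")
    total = b.sum()
    if total == 0:
        return np.zeros_like(b)
    return b / total


def shannon_entropy(p: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy H = −Σ pᵢ log₂ pᵢ in bits; zero terms contribute 0."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    if nz.size == 0:
        return 0.0
    return float(-(nz * np.log2(nz)).sum())


def species_richness(
    p: Sequence[float] | np.ndarray, presence_threshold: float = 0.0
) -> int:
    """Number of organisms present: entries strictly above the threshold."""
    if presence_threshold < 0:
        raise ValueError("presence_threshold must be >= 0")
    p = np.asarray(p, dtype=float)
    return int((p > presence_threshold).sum())


def count_exchanges(records: Iterable[ExchangeRecord]) -> int:
    """Distinct (donor, receiver, metabolite) triples among the records."""
    return len({(r.donor, r.receiver, r.metabolite) for r in records})


def max_possible_exchanges(n_organisms: int, n_metabolites: int) -> int:
    """Upper bound on exchanges: every organism pair transfers every
    metabolite, i.e. C(n_organisms, 2) × n_metabolites; 0 below two organisms."""
    if n_organisms < 2:
        return 0
    return comb(n_organisms, 2) * n_metabolites


def flux_to_organism(
    records: Iterable[ExchangeRecord],
    organism_id: str,
    organism_ids: Sequence[str],
) -> float:
    """Total mmol absorbed by one organism from all others."""
    if organism_id not in organism_ids:
        raise KeyError(f"unknown organism {organism_id!r}")
    return float(sum(r.amount for r in records if r.receiver == organism_id))


def secretion_total(
    secretion_totals: Mapping[str, float], metabolite_id: str
) -> float:
    """Community-wide cumulative secretion of one metabolite (mmol)."""
    if metabolite_id not in secretion_totals:
        raise KeyError(f"metabolite {metabolite_id!r} unknown to this simulation")
    return float(secretion_totals[metabolite_id])
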