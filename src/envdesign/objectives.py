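"""Objective families mapping a phenotype summary to a scalar fitness.

Six families are supported: community Shannon entropy, the relative abundance
of a chosen organism, the total number of metabolic exchanges, the total
metabolic flux directed at a chosen organism, the community-level secretion
of a chosen metabolite, and the approximation of a target composition (sum
squared error to a target abundance vector, e.g. [0.90, 0.05, 0.05]).

Internally the engine always maximises: for minimise-direction families the
raw value is negated, with the raw value preserved for logging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .phenotype_metrics import PhenotypeSummary, secretion_total

__all__ = ["Objective", "sse_to_target", "OBJECTIVE_FAMILIES", "objective_from_dict"]

OBJECTIVE_FAMILIES = (
    "entropy",
    "organism_abundance",
    "total_exchanges",
    "flux_to_organism",
    "metabolite_secretion",
    "target_composition",
)

Direction = Literal["maximize", "minimize"]

_DEFAULT_DIRECTION = {f: "maximize" for f in OBJECTIVE_FAMILIES}
_DEFAULT_DIRECTION["target_composition"] = "minimize"


def sse_to_target(
    p: Sequence[float] | np.ndarray, target: Sequence[float] | np.ndarray
) -> float:
    """Sum squared error Σ (pᵢ − tᵢ)² between achieved and target abundances."""
    p = np.asarray(p, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: abundances {p.shape} vs target {t.shape}")
    return float(((p - t) ** 2).sum())


@dataclass(frozen=True)
class Objective:
    """One scoring family with direction and family-specific parameters.

    ``organism`` is required for organism_abundance / flux_to_organism,
    ``metabolite`` for metabolite_secretion, ``target`` for
    target_composition.  ``direction`` defaults to maximize for all families
    except target_composition, which is minimised.
    """

    family: str
    direction: Direction | None = None
    organism: str | None = None
    metabolite: str | None = None
    target: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in OBJECTIVE_FAMILIES:
            raise ValueError(
                f"unknown objective family {self.family!r}; valid: {OBJECTIVE_FAMILIES}"
            )
        if self.direction is None:
            object.__setattr__(self, "direction", _DEFAULT_DIRECTION[self.family])
        if self.direction not in ("maximize", "minimize"):
            raise ValueError(f"direction must be maximize/minimize, got {self.direction!r}")
        if self.family in ("organism_abundance", "flux_to_organism") and not self.organism:
            raise ValueError(f"family {self.family!r} requires an organism id")
        if self.family == "metabolite_secretion" and not self.metabolite:
            raise ValueError("family 'metabolite_secretion' requires a metabolite id")
        if self.family == "target_composition":
            if self.target is None:
                raise ValueError("family 'target_composition' requires a target vector")
            t = tuple(float(x) for x in self.target)
            if abs(sum(t) - 1.0) > 1e-9:
                raise ValueError(f"target abundances must sum to 1, got {sum(t)}")
            object.__setattr__(self, "target", t)

    def raw(self, summary: PhenotypeSummary) -> float:
        """The family metric on its natural scale (SSE stays an error)."""
        if self.family == "entropy":
            return summary.entropy
        if self.family == "organism_abundance":
            return summary.abundance_of(self.organism)  # type: ignore[arg-type]
        if self.family == "total_exchanges":
            return float(summary.n_exchanges)
        if self.family == "flux_to_organism":
            if self.organism not in summary.organism_ids:
                raise KeyError(f"unknown organism {self.organism!r}")
            return float(summary.flux_to.get(self.organism, 0.0))
        if self.family == "metabolite_secretion":
            return secretion_total(summary.secretion_totals, self.metabolite)  # type: ignore[arg-type]
        if self.family == "target_composition":
            return sse_to_target(summary.abundances, self.target)  # type: ignore[arg-type]
        raise AssertionError(self.family)

    def score(self, summary: PhenotypeSummary) -> float:
        """Fitness under the always-maximize convention (negated if minimised)."""
        raw = self.raw(summary)
        return -raw if self.direction == "minimize" else raw

    def describe(self) -> str:
        parts = [self.family]
        if self.organism:
            parts.append(self.organism)
        if self.metabolite:
            parts.append(self.metabolite)
        return ":".join(parts)


def objective_from_dict(d: dict) -> Objective:
    """Build an Objective from a config block (family, direction, params)."""
    known = {"family", "direction", "organism", "metabolite", "target"}
    extra = set(d) - known
    if extra:
        raise ValueError(f"unknown objective config keys: {sorted(extra)}")
    if "family" not in d:
        raise ValueError(f"objective config requires 'family'; valid: {OBJECTIVE_FAMILIES}")
    target = d.get("target")
    return Objective(
        family=d["family"],
        direction=d.get("direction"),
        organism=d.get("organism"),
        metabolite=d.get("metabolite"),
        target=tuple(target) if target is not None else None,
    )
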