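"""The packaged synthetic study system.

A 13-organism community over a 10-nutrient pool whose complete
environment → phenotype mapping (all subsets of up to 3 nutrients plus the
base medium alone: 176 environments) is small enough to enumerate in seconds,
yet reproduces the statistical structure of exhaustive community screens:
variable species richness, skewed fitness distributions across environments,
organisms that dominate some environments (> 50 % relative abundance),
auxotrophs that fail to grow without cross-fed cofactors, and dense byproduct
exchange networks.  Having the full mapping gives every objective a known
global optimum and a full reference fitness distribution, which is what the
search benchmarks are measured against.

The community is drawn from :func:`envdesign.community_sim.generate_random_community`
at a frozen seed; ``validate_fixture`` re-checks the structural assertions the
fixture is required to satisfy.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .community_sim import (
    Community,
    InoculumSpec,
    Mapping,
    SimulationConfig,
    generate_mapping,
    generate_random_community,
    inoculum_amounts,
)
from .env_space import EnvironmentSpace, MediumSpec, Nutrient, NutrientPool
from .objectives import Objective

__all__ = [
    "FIXTURE_SEED",
    "fixture_pool",
    "fixture_space",
    "fixture_medium_spec",
    "fixture_inoculum",
    "fixture_simulation_config",
    "fixture_community",
    "fixture_mapping",
    "fixture_objectives",
    "validate_fixture",
    "three_species_community",
    "three_species_config",
]

#: Frozen generator seed for the packaged community (see validate_fixture).
FIXTURE_SEED = 1

_FIXTURE_NUTRIENTS = (
    ("glc", "glucose", 6),
    ("fru", "fructose", 6),
    ("gal", "galactose", 6),
    ("xyl", "xylose", 5),
    ("ara", "arabinose", 5),
    ("mal", "maltose", 12),
    ("cit", "citrate", 6),
    ("glyc", "glycerol", 3),
    ("ala", "alanine", 3),
    ("ser", "serine", 3),
)


def fixture_pool() -> NutrientPool:
    """The 10-nutrient pool: sugars, organic acids and amino acids."""
    return NutrientPool(tuple(Nutrient(i, n, c) for i, n, c in _FIXTURE_NUTRIENTS))


def fixture_space() -> EnvironmentSpace:
    """Up to 3 nutrients from the pool, base medium alone included: 176 environments."""
    return EnvironmentSpace(fixture_pool(), max_nutrients=3, include_empty=True)


def fixture_medium_spec() -> MediumSpec:
    """Equimolar split of 50 mM C in 400 µl (0.02 mmol C per environment)."""
    return MediumSpec(total_carbon_concentration=50.0, volume=400.0)


def fixture_inoculum() -> InoculumSpec:
    """OD600 0.05 ≙ 1.6×10⁷ cells in 400 µl at 2.8×10⁻¹³ gDW per cell, 13 ways."""
    return InoculumSpec(od600=0.05, cells_at_od=1.6e7, cell_mass=2.8e-13, n_organisms=13)


def fixture_simulation_config() -> SimulationConfig:
    """24 h, 0.01 h Euler step, death rate 0.1 h⁻¹, equal-ratio inoculum."""
    _, per_org = inoculum_amounts(fixture_inoculum())
    return SimulationConfig(
        duration=24.0, timestep=0.01, death_rate=0.1, inoculum_per_organism=per_org
    )


@lru_cache(maxsize=4)
def fixture_community(seed: int = FIXTURE_SEED) -> Community:
    """The frozen 13-organism community (specialists, generalists,
    cross-feeders and cofactor auxotrophs)."""
    rng = np.random.default_rng(seed)
    return generate_random_community(13, fixture_pool(), rng=rng)


@lru_cache(maxsize=2)
def fixture_mapping(seed: int = FIXTURE_SEED) -> Mapping:
    """The exhaustive 176-environment mapping of the fixture community."""
    return generate_mapping(
        fixture_community(seed),
        fixture_space(),
        fixture_medium_spec(),
        fixture_simulation_config(),
    )


def _grew(mapping: Mapping, config: SimulationConfig) -> np.ndarray:
    """(n_envs, n_organisms) boolean: final biomass above the inoculum."""
    b = np.array([s.final_biomass for s in mapping.summaries()])
    return b > config.inoculum_per_organism


def fixture_objectives(mapping: Mapping | None = None) -> dict[str, Objective]:
    """One representative objective per family, parametrised from the mapping.

    Parameter choices are deterministic and mirror how representative targets
    are chosen in practice: the focal organism is the one whose relative
    abundance varies most across environments, the flux target the organism
    with the most variable incoming exchange flux, the secretion target the
    metabolite with the most variable community output, and the target
    composition puts 90 % on the focal organism and 5 % on the two next most
    variable organisms.
    """
    mapping = mapping or fixture_mapping()
    summaries = mapping.summaries()
    orgs = mapping.organism_ids
    abund = np.array([s.abundances for s in summaries])
    flux = np.array([[s.flux_to[o] for o in orgs] for s in summaries])
    sec = np.array(
        [[s.secretion_totals[m] for m in mapping.metabolite_ids] for s in summaries]
    )
    focal = orgs[int(abund.var(axis=0).argmax())]
    flux_org = orgs[int(flux.var(axis=0).argmax())]
    sec_met = mapping.metabolite_ids[int(sec.var(axis=0).argmax())]
    order = np.argsort(-abund.var(axis=0))
    target = [0.0] * len(orgs)
    target[order[0]] = 0.90
    target[order[1]] = 0.05
    target[order[2]] = 0.05
    return {
        "entropy": Objective(family="entropy"),
        "abundance": Objective(family="organism_abundance", organism=focal),
        "exchanges": Objective(family="total_exchanges"),
        "flux_to": Objective(family="flux_to_organism", organism=flux_org),
        "secretion": Objective(family="metabolite_secretion", metabolite=sec_met),
        "target": Objective(family="target_composition", target=tuple(target)),
    }


def validate_fixture(mapping: Mapping | None = None) -> dict[str, bool]:
    """Structural assertions the packaged fixture must satisfy.

    * some environment lets one organism exceed 50 % relative abundance;
    * every organism has at least one environment in which it did not grow;
    * each of the six objective reference distributions is non-degenerate:
      its maximum strictly exceeds its own 99th percentile, so the
      99th-percentile benchmark is attainable.
    """
    from .benchmark import ReferenceDistribution, percentile_threshold

    mapping = mapping or fixture_mapping()
    config = fixture_simulation_config()
    abund = np.array([s.abundances for s in mapping.summaries()])
    grew = _grew(mapping, config)
    checks = {
        "dominance_environment_exists": bool((abund > 0.5).any()),
        "every_organism_has_zero_growth_environment": bool((~grew).any(axis=0).all()),
    }
    for name, obj in fixture_objectives(mapping).items():
        ref = ReferenceDistribution.from_mapping(mapping, obj)
        checks[f"reference_nondegenerate_{name}"] = bool(
            ref.maximum > percentile_threshold(ref, 99.0)
        )
    return checks


# ---------------------------------------------------------------------------
# Three-species configuration for target-composition search
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4)
def three_species_community(seed: int = FIXTURE_SEED) -> Community:
    """A 3-organism community for on-demand target-composition searches."""
    rng = np.random.default_rng(seed)
    return generate_random_community(
        3,
        fixture_pool(),
        archetype_mix={"specialist": 1 / 3, "generalist": 1 / 3, "cross_feeder": 1 / 3},
        rng=rng,
    )


def three_species_config() -> SimulationConfig:
    """Growth-phase configuration: 1×10⁻⁶ gDW inocula, no death rate; each
    carbon source supplied at a fixed 5×10⁻⁴ mmol (see MediumSpec override)."""
    return SimulationConfig(
        duration=24.0, timestep=0.01, death_rate=0.0, inoculum_per_organism=1e-6
    )
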