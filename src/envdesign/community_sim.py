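"""Seedable consumer–resource community simulator with cross-feeding.

This is the desk-scale evaluator standing behind the environment → phenotype
contract: a Monod consumer–resource model with explicit byproduct secretion,
auxotrophy gates and an optional first-order death rate, integrated by
explicit Euler at a configurable timestep (defaults: 24 h horizon, 0.01 h
step, death rate 0.1 h⁻¹).  It reports exactly the phenotype interface the
search layer consumes — final biomasses, relative abundances, richness,
entropy, donor→receiver exchange records and cumulative secretions.

Model sketch, per organism i and substrate s (pool nutrient or byproduct):

    uptake_is  = Vmax_is · c_s/(Km_is + c_s) · B_i · dt     (capped by supply)
    ΔB_i       = Σ_s yield_is · uptake_is − δ · B_i · dt
    secretion  = fraction f_ism of the consumed carbon of s re-emitted as
                 byproduct m (mmol converted via carbon atoms per molecule)

Growth and uptake are gated to zero while any required cofactor metabolite is
absent from the medium (auxotrophy).  When several organisms compete for one
substrate the per-step demand is rationed proportionally (biomass × Monod
demand), so amounts never go negative.  Carbon is fully accounted: consumed
carbon goes to biomass (via a fixed gDW → mmol-C factor), secreted
byproducts, or an explicit respired bucket; death-removed biomass is tracked
separately, so a global carbon balance holds at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .env_space import (
    Environment,
    EnvironmentSpace,
    MediumSpec,
    NutrientPool,
    build_medium,
    canonical_sort_key,
    enumerate_environments,
)
from .phenotype_metrics import (
    ExchangeRecord,
    PhenotypeSummary,
    relative_abundances,
    shannon_entropy,
    species_richness,
)

__all__ = [
    "UptakeKinetics",
    "OrganismSpec",
    "Community",
    "SimulationConfig",
    "InoculumSpec",
    "SimulationResult",
    "Mapping",
    "inoculum_amounts",
    "simulate_community",
    "growth_stopped",
    "generate_random_community",
    "generate_mapping",
    "DEFAULT_BYPRODUCTS",
    "DEFAULT_COFACTORS",
    "DEFAULT_ARCHETYPE_MIX",
]


@dataclass(frozen=True)
class UptakeKinetics:
    """Monod parameters: Vmax (mmol·gDW⁻¹·h⁻¹) and Km (mM)."""

    vmax: float
    km: float

    def __post_init__(self) -> None:
        if self.vmax < 0 or self.km < 0:
            raise ValueError("vmax and km must be >= 0")


@dataclass(frozen=True)
class OrganismSpec:
    """Growth/uptake/secretion parameters of one organism.

    ``secretion[s][m]`` is the fraction of the carbon consumed from substrate
    s that is re-emitted as byproduct metabolite m; per-substrate fractions
    must sum to at most 1.  ``required_cofactors`` is the auxotrophy gate:
    growth is impossible while any listed metabolite is absent.
    """

    id: str
    uptake: dict[str, UptakeKinetics]
    yields: dict[str, float]  # gDW per mmol of each consumable
    secretion: dict[str, dict[str, float]] = field(default_factory=dict)
    required_cofactors: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for s, y in self.yields.items():
            if y < 0:
                raise ValueError(f"{self.id}: yield for {s!r} must be >= 0")
        for s, fracs in self.secretion.items():
            for m, f in fracs.items():
                if not 0 <= f <= 1:
                    raise ValueError(
                        f"{self.id}: secretion fraction {s}->{m} out of [0,1]: {f}"
                    )
            tot = sum(fracs.values())
            if tot > 1 + 1e-12:
                raise ValueError(
                    f"{self.id}: secretion fractions for {s!r} sum to {tot} > 1"
                )


@dataclass(frozen=True)
class Community:
    """A set of organisms plus carbon counts for their shared metabolites."""

    organisms: tuple[OrganismSpec, ...]
    metabolite_carbon: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [o.id for o in self.organisms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate organism ids in community")

    @property
    def organism_ids(self) -> tuple[str, ...]:
        return tuple(o.id for o in self.organisms)

    def secretable_metabolites(self) -> tuple[str, ...]:
        """Sorted ids of every metabolite some organism can secrete."""
        mets: set[str] = set()
        for o in self.organisms:
            for fracs in o.secretion.values():
                mets.update(fracs)
        return tuple(sorted(mets))


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings for one growth simulation."""

    duration: float = 24.0  # hours
    timestep: float = 0.01  # hours
    death_rate: float = 0.1  # per hour; 0 disables death
    inoculum_per_organism: float = 3.446153846153846e-07  # gDW
    volume: float = 400.0  # microlitres (converts mmol to mM for Monod terms)
    gdw_to_mmol_carbon: float = 40.0  # mmol C per gDW of biomass
    cofactor_threshold: float = 0.0  # mmol strictly above which a cofactor counts as present
    growth_zero_tolerance: float = 1e-12  # gDW per step treated as zero derivative

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not 0 < self.timestep <= self.duration:
            raise ValueError("timestep must satisfy 0 < dt <= duration")
        if self.death_rate < 0:
            raise ValueError("death_rate must be >= 0")
        if self.inoculum_per_organism <= 0:
            raise ValueError("inoculum_per_organism must be > 0")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.timestep))


@dataclass(frozen=True)
class InoculumSpec:
    """Optical-density bookkeeping for the starting biomass."""

    od600: float
    cells_at_od: float  # cell count at that OD in the working volume
    cell_mass: float  # gDW per cell
    n_organisms: int

    def __post_init__(self) -> None:
        if min(self.od600, self.cells_at_od, self.cell_mass) <= 0:
            raise ValueError("od600, cells_at_od and cell_mass must be > 0")
        if self.n_organisms < 1:
            raise ValueError("n_organisms must be >= 1")


def inoculum_amounts(spec: InoculumSpec) -> tuple[float, float]:
    """(total gDW, per-organism gDW) for an equal-ratio inoculum."""
    total = spec.cells_at_od * spec.cell_mass
    return total, total / spec.n_organisms


@dataclass(frozen=True)
class SimulationResult:
    """Trajectories plus cumulative exchange and secretion accounting."""

    organism_ids: tuple[str, ...]
    metabolite_ids: tuple[str, ...]  # every substrate tracked (nutrients + byproducts)
    times: np.ndarray  # (T+1,) hours
    biomass: np.ndarray  # (T+1, n_organisms) gDW
    metabolites: np.ndarray  # (T+1, n_metabolites) mmol
    exchange_records: tuple[ExchangeRecord, ...]
    secretion_by_organism: dict[str, dict[str, float]]  # organism -> metabolite -> mmol
    death_removed_gdw: float
    respired_carbon_mmol: float
    config: SimulationConfig

    @property
    def final_biomass(self) -> np.ndarray:
        return self.biomass[-1]

    def secretion_totals(self, metabolite_ids: Sequence[str] | None = None) -> dict[str, float]:
        """Community-wide cumulative secretion per metabolite (mmol).

        Includes a zero entry for every requested metabolite so that 'never
        secreted' is distinguishable from 'unknown metabolite'.
        """
        mets = set()
        for d in self.secretion_by_organism.values():
            mets.update(d)
        if metabolite_ids is not None:
            mets.update(metabolite_ids)
        totals = {m: 0.0 for m in sorted(mets)}
        for d in self.secretion_by_organism.values():
            for m, v in d.items():
                totals[m] += v
        return totals

    def summary(
        self,
        presence_threshold: float = 0.0,
        secretable_metabolites: Sequence[str] | None = None,
    ) -> PhenotypeSummary:
        """Collapse the run into the phenotype interface the objectives use."""
        b = self.final_biomass
        p = relative_abundances(b)
        flux_to = {o: 0.0 for o in self.organism_ids}
        for r in self.exchange_records:
            flux_to[r.receiver] += r.amount
        return PhenotypeSummary(
            organism_ids=self.organism_ids,
            final_biomass=tuple(float(x) for x in b),
            abundances=tuple(float(x) for x in p),
            richness=species_richness(p, presence_threshold),
            entropy=shannon_entropy(p),
            exchanges=self.exchange_records,
            secretion_totals=self.secretion_totals(secretable_metabolites),
            flux_to=flux_to,
        )


def growth_stopped(
    trajectory: Sequence[float] | np.ndarray, zero_tolerance: float = 1e-12
) -> bool:
    """Two-clause growth-cessation rule on a biomass time series.

    True iff the discrete forward derivative was positive (beyond the zero
    tolerance) at least once — the organism grew — and is non-positive at the
    final step.  An organism that never grew returns False under the literal
    rule; callers wanting to treat non-growers separately should test growth
    first.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.size < 2:
        raise ValueError("trajectory needs at least two points")
    d = np.diff(traj)
    grew = bool((d > zero_tolerance).any())
    stopped_at_end = bool(d[-1] <= zero_tolerance)
    return grew and stopped_at_end


def _union_substrates(
    organisms: Sequence[OrganismSpec], medium: Mapping[str, float]
) -> list[str]:
    subs: set[str] = set(medium)
    for o in organisms:
        subs.update(o.uptake)
        subs.update(o.required_cofactors)
        for fracs in o.secretion.values():
            subs.update(fracs)
    return sorted(subs)


def simulate_community(
    organisms: Sequence[OrganismSpec],
    medium: Mapping[str, float],
    config: SimulationConfig,
    *,
    carbon_atoms: Mapping[str, int],
    inoculum: Sequence[float] | None = None,
) -> SimulationResult:
    """Integrate community growth in one medium; deterministic given inputs.

    ``medium`` maps nutrient id -> initial mmol.  ``carbon_atoms`` must cover
    every substrate any organism touches (pool nutrients and byproducts).
    ``inoculum`` overrides the per-organism starting biomass when given.
    """
    org_ids = tuple(o.id for o in organisms)
    subs = _union_substrates(organisms, medium)
    missing = [s for s in subs if s not in carbon_atoms]
    if missing:
        raise KeyError(
            f"no carbon count declared for substrate(s) {missing}; uptake and "
            "secretion targets must resolve to pool nutrients or declared metabolites"
        )
    n_org, n_sub = len(organisms), len(subs)
    sidx = {s: j for j, s in enumerate(subs)}
    c_sub = np.array([float(carbon_atoms[s]) for s in subs])

    vmax = np.zeros((n_org, n_sub))
    km = np.zeros((n_org, n_sub))
    Y = np.zeros((n_org, n_sub))
    F = np.zeros((n_org, n_sub, n_sub))  # carbon fraction substrate -> byproduct
    cof = np.zeros((n_org, n_sub), dtype=bool)
    for i, o in enumerate(organisms):
        for s, kin in o.uptake.items():
            vmax[i, sidx[s]] = kin.vmax
            km[i, sidx[s]] = kin.km
        for s, y in o.yields.items():
            Y[i, sidx[s]] = y
        for s, fracs in o.secretion.items():
            for m, f in fracs.items():
                F[i, sidx[s], sidx[m]] = f
        for m in o.required_cofactors:
            cof[i, sidx[m]] = True

    dt = config.timestep
    n_steps = config.n_steps
    vol_l = config.volume * 1e-6
    kappa = config.gdw_to_mmol_carbon

    B = np.full(n_org, config.inoculum_per_organism)
    if inoculum is not None:
        B = np.asarray(inoculum, dtype=float).copy()
        if B.shape != (n_org,):
            raise ValueError("inoculum must have one entry per organism")
    M = np.zeros(n_sub)
    for s, amt in medium.items():
        if amt < 0:
            raise ValueError(f"negative medium amount for {s!r}")
        M[sidx[s]] = amt

    biomass_traj = np.empty((n_steps + 1, n_org))
    met_traj = np.empty((n_steps + 1, n_sub))
    biomass_traj[0] = B
    met_traj[0] = M

    cum_secretion = np.zeros((n_org, n_sub))
    exchange = np.zeros((n_org, n_org, n_sub))  # donor, receiver, metabolite
    death_removed = 0.0
    respired = 0.0

    ones = np.ones(n_sub)
    for t in range(1, n_steps + 1):
        gate = np.all(~cof | (M > config.cofactor_threshold)[None, :], axis=1)
        conc = M / vol_l  # mmol / L == mM
        denom = km + conc[None, :]
        monod = np.divide(conc[None, :], denom, out=np.zeros_like(denom), where=denom > 0)
        demand = vmax * monod * (B * gate)[:, None] * dt
        total = demand.sum(axis=0)
        scale = np.ones_like(ones)
        over = total > M
        np.divide(M, total, out=scale, where=over)
        uptake = demand * scale[None, :]

        carbon_in = uptake * c_sub[None, :]  # mmol C consumed per (org, substrate)
        sec = np.einsum("os,osm->om", carbon_in, F) / c_sub[None, :]
        growth = (uptake * Y).sum(axis=1)
        respired += carbon_in.sum() - growth.sum() * kappa - (sec * c_sub[None, :]).sum()

        # Exchange attribution: absorbed byproducts credited to donors in
        # proportion to their cumulative secretion so far (pool is well mixed).
        donor_tot = cum_secretion.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(donor_tot[None, :] > 0, cum_secretion / donor_tot[None, :], 0.0)
        if w.any():
            exchange += np.einsum("dm,rm->drm", w, uptake)

        cum_secretion += sec
        M = M - uptake.sum(axis=0) + sec.sum(axis=0)
        assert M.size == 0 or M.min() > -1e-9, "substrate driven negative — rationing failed"
        np.maximum(M, 0.0, out=M)
        dead = config.death_rate * B * dt
        death_removed += dead.sum()
        B = B + growth - dead
        biomass_traj[t] = B
        met_traj[t] = M

    records: list[ExchangeRecord] = []
    for d in range(n_org):
        for r in range(n_org):
            if d == r:
                continue
            for j in range(n_sub):
                amt = exchange[d, r, j]
                if amt > 0:
                    records.append(
                        ExchangeRecord(org_ids[d], org_ids[r], subs[j], float(amt))
                    )

    secretion_by_org = {
        org_ids[i]: {
            subs[j]: float(cum_secretion[i, j])
            for j in range(n_sub)
            if cum_secretion[i, j] > 0
        }
        for i in range(n_org)
    }
    return SimulationResult(
        organism_ids=org_ids,
        metabolite_ids=tuple(subs),
        times=np.arange(n_steps + 1) * dt,
        biomass=biomass_traj,
        metabolites=met_traj,
        exchange_records=tuple(records),
        secretion_by_organism=secretion_by_org,
        death_removed_gdw=float(death_removed),
        respired_carbon_mmol=float(respired),
        config=config,
    )


def carbon_balance(result: SimulationResult, carbon_atoms: Mapping[str, int]) -> np.ndarray:
    """Total accounted carbon (mmol C) at the first and last time point.

    biomass C + medium/byproduct C + death-removed C + respired C; the two
    entries agree to rounding when the model conserves carbon.
    """
    kappa = result.config.gdw_to_mmol_carbon
    c = np.array([float(carbon_atoms[s]) for s in result.metabolite_ids])
    start = result.biomass[0].sum() * kappa + result.metabolites[0] @ c
    end = (
        result.biomass[-1].sum() * kappa
        + result.metabolites[-1] @ c
        + result.death_removed_gdw * kappa
        + result.respired_carbon_mmol
    )
    return np.array([start, end])


# ---------------------------------------------------------------------------
# Synthetic community generation
# ---------------------------------------------------------------------------

DEFAULT_BYPRODUCTS: dict[str, int] = {
    "acetate": 2,
    "formate": 1,
    "lactate": 3,
    "ethanol": 2,
    "glycine": 2,
    "butyrate": 4,
}

#: Cofactor metabolites auxotrophs may require (secreted in trace amounts).
DEFAULT_COFACTORS: dict[str, int] = {
    "methionine": 5,
    "thiamine": 12,
}

DEFAULT_ARCHETYPE_MIX: dict[str, float] = {
    "specialist": 0.3,
    "generalist": 0.25,
    "cross_feeder": 0.25,
    "auxotroph": 0.2,
}


def _archetype_counts(
    n: int, mix: Mapping[str, float], rng: np.random.Generator
) -> list[str]:
    names = list(mix)
    props = np.array([mix[k] for k in names], dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("archetype proportions must be >= 0 and sum to 1")
    counts = np.floor(props * n).astype(int)
    # guarantee one of each requested archetype when n permits
    requested = props > 0
    while requested.sum() <= n and (counts[requested] == 0).any():
        counts[np.flatnonzero(requested & (counts == 0))[0]] += 1
    while counts.sum() > n:
        counts[counts.argmax()] -= 1
    while counts.sum() < n:
        counts[(props - counts / max(n, 1)).argmax()] += 1
    roles = [name for name, k in zip(names, counts) for _ in range(int(k))]
    rng.shuffle(roles)
    return roles


def _pick(rng: np.random.Generator, items: Sequence[str], k: int) -> list[str]:
    k = min(k, len(items))
    idx = rng.choice(len(items), size=k, replace=False)
    return [items[i] for i in sorted(idx)]


def generate_random_community(
    n_organisms: int,
    pool: NutrientPool,
    archetype_mix: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
    *,
    byproducts: Mapping[str, int] | None = None,
    cofactors: Mapping[str, int] | None = None,
    gdw_to_mmol_carbon: float = 40.0,
) -> Community:
    """A reproducible random community with the archetype structure of real
    isolate collections: specialists, generalists, byproduct cross-feeders and
    auxotrophs whose required cofactor is secretable by another member.

    Yields are derived carbon-closed — biomass carbon equals consumed carbon
    minus secreted carbon (divided by ``gdw_to_mmol_carbon``) — so simulations
    of generated communities conserve carbon with zero respiration.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    mix = dict(archetype_mix or DEFAULT_ARCHETYPE_MIX)
    byp = dict(byproducts or DEFAULT_BYPRODUCTS)
    cofs = dict(cofactors or DEFAULT_COFACTORS)
    carbon = {**pool.carbon_atoms(), **byp, **cofs}
    nutrient_ids = list(pool.ids)
    byp_ids = sorted(byp)
    cof_ids = sorted(cofs)

    roles = _archetype_counts(n_organisms, mix, rng)
    organisms: list[OrganismSpec] = []
    used_cofactors: list[tuple[int, str]] = []  # (organism index, cofactor id)

    for i, role in enumerate(roles):
        oid = f"org{i + 1:02d}"
        uptake: dict[str, UptakeKinetics] = {}
        secretion: dict[str, dict[str, float]] = {}
        required: frozenset[str] = frozenset()

        if role == "specialist":
            nuts = _pick(rng, nutrient_ids, int(rng.integers(1, 3)))
            vm_lo, vm_hi = 8.0, 15.0
        elif role == "generalist":
            nuts = _pick(rng, nutrient_ids, int(rng.integers(4, 8)))
            vm_lo, vm_hi = 3.0, 8.0
        elif role == "cross_feeder":
            nuts = _pick(rng, nutrient_ids, int(rng.integers(1, 4)))
            vm_lo, vm_hi = 5.0, 12.0
        elif role == "auxotroph":
            nuts = _pick(rng, nutrient_ids, int(rng.integers(2, 5)))
            vm_lo, vm_hi = 6.0, 12.0
            cofactor = cof_ids[int(rng.integers(len(cof_ids)))]
            required = frozenset({cofactor})
            used_cofactors.append((i, cofactor))
        else:
            raise ValueError(f"unknown archetype {role!r}")

        for s in nuts:
            uptake[s] = UptakeKinetics(
                vmax=float(rng.uniform(vm_lo, vm_hi)),
                km=float(rng.uniform(0.01, 0.2)),
            )
        if role == "cross_feeder":
            for m in _pick(rng, byp_ids, int(rng.integers(1, 3))):
                uptake[m] = UptakeKinetics(
                    vmax=float(rng.uniform(5.0, 12.0)), km=float(rng.uniform(0.01, 0.1))
                )

        # each consumed substrate sheds 1-2 byproducts, 10-45 % of its carbon
        for s in uptake:
            out = _pick(rng, [m for m in byp_ids if m != s], int(rng.integers(1, 3)))
            fracs = rng.uniform(0.05, 0.45 / len(out), size=len(out))
            secretion[s] = {m: float(f) for m, f in zip(out, fracs)}

        organisms.append(
            OrganismSpec(
                id=oid,
                uptake=uptake,
                yields={},
                secretion=secretion,
                required_cofactors=required,
            )
        )

    # every auxotroph's cofactor must be secretable by some other organism:
    # bolt a trace cofactor secretion onto a random non-auxotroph's substrate
    for i, cofactor in used_cofactors:
        donors = [
            j
            for j, o in enumerate(organisms)
            if j != i and cofactor not in o.required_cofactors and o.uptake
        ]
        j = donors[int(rng.integers(len(donors)))]
        donor = organisms[j]
        s = sorted(donor.uptake)[int(rng.integers(len(donor.uptake)))]
        sec = {k: dict(v) for k, v in donor.secretion.items()}
        block = sec.setdefault(s, {})
        block[cofactor] = block.get(cofactor, 0.0) + float(rng.uniform(0.01, 0.03))
        organisms[j] = replace(donor, secretion=sec)

    # carbon-closed yields: biomass carbon = consumed - secreted carbon
    closed: list[OrganismSpec] = []
    for o in organisms:
        yields = {}
        for s in o.uptake:
            shed = sum(o.secretion.get(s, {}).values())
            yields[s] = (1.0 - shed) * carbon[s] / gdw_to_mmol_carbon
        closed.append(replace(o, yields=yields))

    return Community(
        organisms=tuple(closed), metabolite_carbon={**byp, **cofs}
    )


# ---------------------------------------------------------------------------
# Exhaustive environment -> phenotype mapping
# ---------------------------------------------------------------------------


@dataclass
class Mapping:
    """Exhaustive environment → phenotype table over an enumerable space.

    Entries are stored in canonical environment order; ``evaluator()`` turns
    the table into a lookup-based evaluator for the search engine.
    """

    organism_ids: tuple[str, ...]
    metabolite_ids: tuple[str, ...]  # secretable metabolites (summary columns)
    entries: list[tuple[Environment, PhenotypeSummary]]

    def __post_init__(self) -> None:
        self._by_env = {env.nutrient_ids: s for env, s in self.entries}
        self._by_id = {env.env_id: (env, s) for env, s in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, env: Environment) -> PhenotypeSummary:
        try:
            return self._by_env[env.nutrient_ids]
        except KeyError:
            raise KeyError(f"environment {env.label() or '(empty)'} not in mapping") from None

    def by_env_id(self, env_id: str) -> tuple[Environment, PhenotypeSummary]:
        return self._by_id[env_id]

    def evaluator(self) -> Callable[[Environment], PhenotypeSummary]:
        return self.lookup

    def environments(self) -> list[Environment]:
        return [env for env, _ in self.entries]

    def summaries(self) -> list[PhenotypeSummary]:
        return [s for _, s in self.entries]


def generate_mapping(
    community: Community,
    space: EnvironmentSpace,
    medium_spec: MediumSpec,
    config: SimulationConfig,
    *,
    cap: int = 100_000,
    presence_threshold: float = 0.0,
) -> Mapping:
    """Simulate every environment of an enumerable space, in canonical order.

    Deterministic: the simulator has no randomness, so re-running with the
    same inputs reproduces the table exactly.
    """
    envs = enumerate_environments(space, cap=cap)
    envs.sort(key=lambda e: canonical_sort_key(e, space.pool))
    carbon = {**space.pool.carbon_atoms(), **community.metabolite_carbon}
    secretable = community.secretable_metabolites()
    entries = []
    for env in envs:
        medium = build_medium(env, medium_spec, space.pool)
        result = simulate_community(
            community.organisms, medium, config, carbon_atoms=carbon
        )
        entries.append(
            (env, result.summary(presence_threshold, secretable_metabolites=secretable))
        )
    return Mapping(
        organism_ids=community.organism_ids,
        metabolite_ids=secretable,
        entries=entries,
    )
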