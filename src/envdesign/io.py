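"""File formats: nutrient pools, community specs, mappings, run logs.

All formats are plain text and round-trip losslessly:

* nutrient pool — CSV with header ``id,name,carbon_atoms``;
* community spec — YAML/JSON, one entry per organism with
  uptake/yield/secretion/cofactor blocks plus a metabolite carbon table;
* mapping — CSV keyed by ``env_id`` (stable hash of the sorted nutrient set)
  with per-organism biomass/abundance, richness, entropy, exchange count,
  per-organism incoming flux and per-metabolite secretion columns, plus a
  companion exchange CSV ``env_id,donor,receiver,metabolite,amount_mmol``;
* run log — one CSV row per (generation, member) with raw objective value and
  fitness, plus a JSON run summary and a replayable JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .community_sim import (
    Community,
    Mapping,
    OrganismSpec,
    SimulationConfig,
    UptakeKinetics,
)
from .env_space import Environment, MediumSpec, Nutrient, NutrientPool
from .ga_engine import GAHistory
from .objectives import Objective
from .phenotype_metrics import ExchangeRecord, PhenotypeSummary

__all__ = [
    "read_pool_csv",
    "write_pool_csv",
    "write_environments_csv",
    "community_to_dict",
    "community_from_dict",
    "save_community",
    "load_community",
    "write_mapping_csv",
    "read_mapping_csv",
    "write_run_log",
    "run_summary_dict",
    "write_run_summary",
    "write_manifest",
]


def read_pool_csv(path: str | Path) -> NutrientPool:
    df = pd.read_csv(path, dtype={"id": str, "name": str})
    for col in ("id", "name", "carbon_atoms"):
        if col not in df.columns:
            raise ValueError(f"pool CSV {path}: missing required column {col!r}")
    nutrients = [
        Nutrient(row.id, row.name, int(row.carbon_atoms)) for row in df.itertuples()
    ]
    return NutrientPool(tuple(nutrients))


def write_pool_csv(pool: NutrientPool, path: str | Path) -> None:
    pd.DataFrame(
        [(n.id, n.name, n.carbon_atoms) for n in pool],
        columns=["id", "name", "carbon_atoms"],
    ).to_csv(path, index=False)


def write_environments_csv(envs: list[Environment], path: str | Path) -> None:
    pd.DataFrame(
        [(e.env_id, e.label()) for e in envs], columns=["env_id", "nutrients"]
    ).to_csv(path, index=False)


# -- community specs --------------------------------------------------------


def community_to_dict(community: Community) -> dict[str, Any]:
    return {
        "metabolites": {m: int(c) for m, c in sorted(community.metabolite_carbon.items())},
        "organisms": [
            {
                "id": o.id,
                "uptake": {
                    s: {"vmax": k.vmax, "km": k.km} for s, k in sorted(o.uptake.items())
                },
                "yields": {s: y for s, y in sorted(o.yields.items())},
                "secretion": {
                    s: dict(sorted(fr.items())) for s, fr in sorted(o.secretion.items())
                },
                "required_cofactors": sorted(o.required_cofactors),
            }
            for o in community.organisms
        ],
    }


def community_from_dict(d: dict[str, Any]) -> Community:
    organisms = tuple(
        OrganismSpec(
            id=o["id"],
            uptake={s: UptakeKinetics(k["vmax"], k["km"]) for s, k in o["uptake"].items()},
            yields={s: float(y) for s, y in o.get("yields", {}).items()},
            secretion={
                s: {m: float(f) for m, f in fr.items()}
                for s, fr in o.get("secretion", {}).items()
            },
            required_cofactors=frozenset(o.get("required_cofactors", ())),
        )
        for o in d["organisms"]
    )
    return Community(
        organisms=organisms,
        metabolite_carbon={m: int(c) for m, c in d.get("metabolites", {}).items()},
    )


def save_community(community: Community, path: str | Path) -> None:
    path = Path(path)
    d = community_to_dict(community)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=1, sort_keys=False))


def load_community(path: str | Path) -> Community:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return community_from_dict(d)


# -- mappings ----------------------------------------------------------------


def write_mapping_csv(
    mapping: Mapping, path: str | Path, exchanges_path: str | Path
) -> None:
    rows = []
    xrows = []
    for env, s in mapping.entries:
        row: dict[str, Any] = {"env_id": env.env_id, "nutrients": env.label()}
        for o, b in zip(s.organism_ids, s.final_biomass):
            row[f"biomass_{o}"] = b
        for o, a in zip(s.organism_ids, s.abundances):
            row[f"abundance_{o}"] = a
        row["richness"] = s.richness
        row["entropy"] = s.entropy
        row["n_exchanges"] = s.n_exchanges
        for o in s.organism_ids:
            row[f"flux_to_{o}"] = s.flux_to.get(o, 0.0)
        for m in mapping.metabolite_ids:
            row[f"secretion_{m}"] = s.secretion_totals.get(m, 0.0)
        rows.append(row)
        for r in s.exchanges:
            xrows.append((env.env_id, r.donor, r.receiver, r.metabolite, r.amount))
    pd.DataFrame(rows).to_csv(path, index=False)
    pd.DataFrame(
        xrows, columns=["env_id", "donor", "receiver", "metabolite", "amount_mmol"]
    ).to_csv(exchanges_path, index=False)


def read_mapping_csv(path: str | Path, exchanges_path: str | Path) -> Mapping:
    df = pd.read_csv(path, dtype={"env_id": str}, float_precision="round_trip")
    df["nutrients"] = df["nutrients"].fillna("")
    xdf = pd.read_csv(
        exchanges_path, dtype={"env_id": str}, float_precision="round_trip"
    )
    organism_ids = tuple(
        c[len("biomass_") :] for c in df.columns if c.startswith("biomass_")
    )
    metabolite_ids = tuple(
        c[len("secretion_") :] for c in df.columns if c.startswith("secretion_")
    )
    by_env_x: dict[str, list[ExchangeRecord]] = {}
    for r in xdf.itertuples():
        by_env_x.setdefault(r.env_id, []).append(
            ExchangeRecord(r.donor, r.receiver, r.metabolite, float(r.amount_mmol))
        )
    entries = []
    for row in df.itertuples():
        env = Environment.from_ids(row.nutrients.split(";") if row.nutrients else [])
        d = row._asdict()
        s = PhenotypeSummary(
            organism_ids=organism_ids,
            final_biomass=tuple(float(d[f"biomass_{o}"]) for o in organism_ids),
            abundances=tuple(float(d[f"abundance_{o}"]) for o in organism_ids),
            richness=int(row.richness),
            entropy=float(row.entropy),
            exchanges=tuple(by_env_x.get(row.env_id, ())),
            secretion_totals={
                m: float(d[f"secretion_{m}"]) for m in metabolite_ids
            },
            flux_to={o: float(d[f"flux_to_{o}"]) for o in organism_ids},
        )
        entries.append((env, s))
    return Mapping(
        organism_ids=organism_ids, metabolite_ids=metabolite_ids, entries=entries
    )


# -- run logs, summaries, manifests -----------------------------------------


def write_run_log(history: GAHistory, path: str | Path) -> None:
    rows = []
    for g, pop in enumerate(history.generations, start=1):
        for m in pop.members:
            rows.append(
                {
                    "generation": g,
                    "env_id": m.env.env_id,
                    "nutrients": m.env.label(),
                    "raw": m.raw,
                    "fitness": m.fitness,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def run_summary_dict(history: GAHistory, objective: Objective) -> dict[str, Any]:
    return {
        "objective": objective.describe(),
        "direction": objective.direction,
        "best_env_id": history.best_environment.env_id,
        "best_nutrients": history.best_environment.label(),
        "best_fitness": history.best_fitness,
        "generations": history.n_generations,
        "unique_evaluations": history.unique_evaluations,
        "total_evaluations": history.total_evaluations,
        "converged": history.converged,
        "criterion_flags": history.criterion_flags,
        "terminated": history.terminated,
        "n_failures": len(history.failures),
    }


def write_run_summary(history: GAHistory, objective: Objective, path: str | Path) -> None:
    Path(path).write_text(json.dumps(run_summary_dict(history, objective), indent=1))


def write_manifest(
    path: str | Path,
    *,
    config: dict[str, Any],
    seed: int | None,
    inputs: dict[str, str] | None = None,
    outputs: list[str] | None = None,
) -> None:
    """Replay manifest: config snapshot, seed, package version, input digests.

    Written before any output so a run can always be reproduced exactly.
    """
    import hashlib

    digests = {}
    for name, p in (inputs or {}).items():
        digests[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
    manifest = {
        "package": "envdesign",
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_digests": digests,
        "outputs": outputs or [],
    }
    Path(path).write_text(json.dumps(manifest, indent=1))


def simulation_config_from_dict(d: dict[str, Any]) -> SimulationConfig:
    return SimulationConfig(**d)


def medium_spec_from_dict(d: dict[str, Any]) -> MediumSpec:
    return MediumSpec(**d)
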