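# envdesign

Designing a synthetic microbial community usually means engineering the
organisms.  `envdesign` takes the complementary route: keep the organisms
fixed and search the *environment* — the combination of limiting carbon
sources added to a base medium — for compositions that push the community
toward a target phenotype.  The obstacle is combinatorial: screening all
subsets of just 20 nutrients already means 2²⁰ ≈ 1.05 million experiments,
and exactly-3-of-154 spaces hold ~6×10⁵ media.  The package is for
computational and synthetic ecologists who want to search such spaces with an
experimentally tractable number of evaluations, in simulation or alongside a
wet-lab screen.

## What it implements

**Search.** An elitist genetic algorithm over nutrient subsets.  Each
generation evaluates a population of P environments (default 10), ranks them
by an objective, carries the top σ (default 2) over as parents, fills the
remaining P−σ slots with random assortments of the pooled parent nutrients
(crossover probability p_C = 0.9, otherwise a fresh random medium), and
mutates every nutrient of every environment except the top-ranked one with
probability p_M = 0.35 into a nutrient not already present.  The run stops
when three criteria hold jointly — (best − mean)/mean < 0.10 within the
generation, |best_ever − best|/|best_ever| < 0.01, and no one-tailed-Welch-
significant fitness increase for 10 consecutive generations — or after G
generations.  Evaluations are memoised, so the history reports the number of
unique experiments actually spent.  A seed-matched, fitness-blind random
baseline provides the control.

**Objectives.**  Six families score a community phenotype: Shannon entropy
H = −Σᵢ pᵢ log₂ pᵢ over relative abundances (taxonomic balance), the
abundance of a chosen organism, the number of distinct metabolic exchanges
(donor, receiver, metabolite), the exchange flux directed at a chosen
organism, the community-level secretion of a chosen metabolite, and the sum
squared error to a target composition such as [0.90, 0.05, 0.05]
(minimised).

**Evaluation.**  Environments are scored either from a precomputed
environment → phenotype lookup table or on demand by the packaged
consumer–resource simulator: Monod uptake kinetics, byproduct secretion as
carbon fractions, cofactor auxotrophies that gate growth, competition by
proportional rationing, an optional first-order death rate, and full carbon
accounting — integrated by explicit Euler (24 h, 0.01 h steps by default).
The simulator is the desk-scale stand-in for genome-scale dynamic FBA
evaluators behind the same interface, and any callable mapping an
environment to a phenotype summary (including a wet-lab pipeline) can take
its place.

**Benchmarking.**  On an enumerable space the full fitness distribution is
known, so runs are scored by G99 (generations until the best solution
strictly exceeds the 99th percentile of all solutions), Prend (percentile of
the best-ever solution at the final generation), and the combined score
S = (1 − G99~) + Prend~ ∈ [0, 2].  A [p_C, p_M] grid search with multi-seed
aggregation identifies robust operating points.

**Packaged fixture.**  A seeded 13-organism community (specialists,
generalists, cross-feeders, auxotrophs) over a 10-nutrient pool whose
complete 176-environment mapping (≤ 3 nutrients, base medium included) is
generated at run time — every benchmark has a known global optimum.

## Worked example

`examples/03_run_ga_for_taxonomic_balance.py` searches the packaged fixture
for the most taxonomically balanced community:

```
best environment: ara
best entropy 3.7004 bits (enumerated optimum 3.7004)
converged: True after 13 generations
unique experiments: 20 of 176 possible
crossed the 99th percentile at generation 1; final percentile 100.0
```

The GA found the enumerated optimum (a single-nutrient arabinose medium,
entropy 3.70 bits over 13 organisms) while explicitly evaluating only 20 of
the 176 possible media.  The other examples cover space counting and medium
construction (`01`), direct community simulation with exchange records
(`02`), GA-vs-random benchmarking with G99/Prend (`04`), and an on-demand
90/5/5 target-composition search with a 3-species community (`05`).  Each
runs in seconds to ~2 minutes with plain `python examples/<name>.py`.

A thin CLI wraps the same library for shell use:

```bash
envdesign fixture --out-dir runs/fixture           # write pool, community, mapping
envdesign enumerate runs/fixture/pool.csv -k 3 --include-empty --count-only
envdesign run-ga --config config.yaml --out-dir runs/ga --seed 1
envdesign benchmark --config config.yaml --out-dir runs/bench --n-seeds 50
```

where `config.yaml` names the space, evaluator (lookup table or simulator),
objective, GA parameters and convergence thresholds; every run writes a
replay manifest first.

## Layout

- `src/envdesign/env_space.py` — nutrient pools, environment spaces, counting,
  enumeration, sampling, medium construction
- `src/envdesign/community_sim.py` — the consumer–resource simulator, synthetic
  community generator, exhaustive mapping
- `src/envdesign/phenotype_metrics.py` — abundances, entropy, richness,
  exchange accounting
- `src/envdesign/objectives.py` — the six objective families
- `src/envdesign/ga_engine.py` — GA operators, convergence, random baseline
- `src/envdesign/benchmark.py` — G99 / Prend / S, grid search, aggregation
- `src/envdesign/fixture.py` — the packaged study system
- `src/envdesign/io.py`, `src/envdesign/cli.py` — file formats and the CLI

See `docs/methods.md` for the model, parameter choices and limitations.
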