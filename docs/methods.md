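# Methods

## Problem setting

An *environment* is a set of limiting carbon sources added to a fixed,
non-limiting base medium (nitrogen, phosphorus, sulfur, ions and water are
assumed in excess and are not modelled).  Given a pool of n nutrients and a
cap N on how many may be combined, the candidate space is the family of
nutrient subsets of admissible size.  Two size rules are exposed because both
occur in practice: `up_to` (sizes 1..N, optionally including the empty
base-medium-only environment) and `exact` (size N only).  Counting is always
closed form — Σ C(n, k) — and enumeration refuses to materialise spaces above
an explicit cap, since large spaces are meant to be searched, not mapped.

A medium is built from an environment in one of two modes.  Default: all
nutrients share one molar amount x with x · Σ carbon_atoms equal to the total
carbon budget (50 mM C × 400 µl = 0.02 mmol C by default), i.e. equimolar
nutrients, fixed total carbon.  Override: every nutrient at a fixed amount
(5×10⁻⁴ mmol in the growth-phase configuration), used when limiting the
length of the growth phase matters more than equalising carbon.

## Community simulator

The evaluator contract is: environment in, phenotype summary out (final
biomasses, relative abundances, richness, Shannon entropy in bits, exchange
records, secretion totals, per-organism incoming flux).  The packaged
evaluator filling that contract is a deterministic consumer–resource model,
not a genome-scale metabolic reconstruction; it is designed to reproduce the
*interface and statistical structure* of mechanistic community simulators at
desk scale, with explicit Euler integration (default 24 h horizon, dt = 0.01
h, and a death rate of 0.1 h⁻¹; the growth-phase configuration uses no death
rate).

Per step, organism i takes up substrate s (pool nutrient or byproduct) at
Vmax·c/(Km+c)·B_i·dt, with concentrations derived from mmol amounts via the
working volume (400 µl).  When joint demand exceeds supply, uptake is
rationed proportionally to demand (biomass × Monod term), which caps amounts
at zero by construction.  Consumed carbon splits three ways: a fraction
f_{s→m} is re-emitted as byproduct m (converted mmol-to-mmol through carbon
atoms per molecule), biomass grows by yield·uptake, and any remainder is
booked as respired carbon.  Biomass carbon uses a single configurable factor
of 40 mmol C per gDW (≈ 48 % carbon by dry weight).  Death removes biomass at
death_rate·B·dt into a separate bucket.  The invariant tested across
randomised communities is exact carbon closure: biomass C + medium C +
death-removed C + respired C is constant to 10⁻⁶ relative tolerance, and no
state variable ever goes negative.

Auxotrophy is a gate, not a stoichiometry: an organism with required
cofactors has growth and uptake zeroed while any cofactor is absent from the
medium (strictly positive amount required; the threshold is configurable).
Cofactors are not consumed — they act catalytically — which keeps the gate
independent of the carbon bookkeeping.

Exchange attribution: the extracellular pool is well mixed, so when an
organism absorbs a byproduct, the absorbed amount is credited to donors in
proportion to their cumulative secretion of that metabolite up to that step.
Self-recycling (an organism re-absorbing its own secretion) is excluded from
exchange records, whose invariant is donor ≠ receiver and amount > 0.  One
*exchange* is a distinct (donor, receiver, metabolite) triple regardless of
amount; the ceiling for n organisms and m metabolites is C(n,2)·m when each
unordered pair transfers each metabolite in one net direction, which is how
the simulator reports (net transfer over the whole run).

Growth cessation follows a two-clause rule on discrete forward differences
with a 10⁻¹² gDW zero tolerance: the organism grew at least once, and the
final derivative is non-positive.  The rule deliberately returns False for
organisms that never grew; callers should classify non-growers separately
(the fixture validation does, using final biomass above the inoculum).

A note on richness: with a death rate, biomass decays exponentially but never
reaches exactly zero, so the default presence threshold of 0 counts decaying
inocula as present.  Richness is therefore reported but not used as an
objective; a positive threshold (e.g. a fraction of the inoculum) can be
passed wherever richness matters.

## Synthetic communities and the packaged fixture

`generate_random_community` draws organisms from four archetypes —
specialists (1–2 nutrients, high Vmax), generalists (4–7 nutrients, moderate
Vmax), cross-feeders (also consume 1–2 byproducts) and auxotrophs (gated on a
cofactor) — with Vmax in 3–15 mmol gDW⁻¹ h⁻¹, Km in 0.01–0.2 mM (so the
~1–7 mM starting concentrations are near-saturating, as in batch culture),
and 1–2 byproducts per consumed substrate carrying 10–45 % of its carbon.
Every auxotroph's cofactor is secretable by at least one other organism (a
trace 1–3 % carbon fraction bolted onto a donor), so auxotroph growth is
contingent on who else grows — the mechanism behind environment-dependent
non-growers.  Yields are derived carbon-closed, yield_s = (1 − Σf)·c_s/κ, so
generated communities respire nothing and the conservation invariant holds
with zero slack; hand-written communities with smaller yields are also valid,
with the gap booked as respiration.

The packaged fixture freezes seed 1 of this generator: 13 organisms over a
10-nutrient pool (sugars, organic acids, amino acids; 3–12 carbons), mapped
exhaustively over all 176 environments of up to 3 nutrients (base medium
included), with the OD-derived inoculum (1.6×10⁷ cells × 2.8×10⁻¹³ gDW split
13 ways).  The scale was chosen so the full mapping builds in about a minute
on one CPU and 50-seed benchmarks run in seconds, while every objective
retains a known enumerated optimum.  `validate_fixture` re-checks the frozen
seed's contract: at least one environment with a > 50 % dominant organism,
at least one zero-growth environment per organism, and a non-degenerate
reference distribution (maximum strictly above its own 99th percentile) for
each of the six objective families.  What passing these benchmarks shows is
that the search machinery works against a community with realistic
qualitative structure; it does not show that the surrogate's quantitative
phenotypes match any particular real community, which would require a
mechanistic (e.g. genome-scale) evaluator behind the same interface.

Representative objective parameters are derived from the mapping itself, not
hand-picked: the focal organism maximises abundance variance across
environments, the flux target maximises incoming-flux variance, the
secretion target maximises community-output variance, and the target
composition assigns 0.90/0.05/0.05 to the three most variable organisms.

## Search engine

Environments are unordered nutrient sets; the GA's slot view appears only
inside the operators.  Design choices on points the high-level recipe leaves
open:

- **Ranking and ties.**  Members sort by fitness under an always-maximise
  convention (minimised objectives are negated; raw values are kept for
  logs), with ties broken by canonical order (subset size, then pool
  indices), making runs fully reproducible.
- **Crossover.**  p_C applies per offspring: with probability p_C the child
  is a random assortment (size uniform on 1..N, capped by availability)
  drawn without replacement from the union of parent nutrients; otherwise it
  is a fresh random environment, which keeps exploration alive at low p_C.
- **Mutation.**  Applied to every environment except the top-ranked one;
  each nutrient is independently replaced with probability p_M by a uniform
  choice among nutrients not currently in that environment (no duplicates;
  an environment already containing the whole pool is left unchanged).
  p_M is restricted below 0.5 so mutation cannot out-pace selection.
- **Initialisation** draws subset sizes uniformly over 1..N, then uniform
  subsets, so small and large media are equally represented.  Duplicate
  population members are allowed; the evaluation memo ensures unique
  experiments are counted once.
- **Convergence.**  Criterion 1 (internal consistency) and 2 (stagnation)
  shift scores by |min|+1 whenever a denominator would be zero or negative —
  necessary because SSE-based fitness is 0 at its optimum.  Criterion 3 runs
  a one-tailed two-sample Welch t-test (α = 0.05) on consecutive
  generations' fitness vectors for each of the last 10 generations; a zero
  variance on both sides counts as no increase when means are equal and as a
  definite increase when the later mean is strictly larger.
- **Failures.**  An evaluator exception assigns a sentinel worst fitness,
  records the failure, and the run continues.

The random baseline keeps every bookkeeping path identical but is
fitness-blind: σ slots re-sampled uniformly (with replacement) from all
previously proposed environments and P−σ fresh random environments, i.e.
novelty enters exactly where crossover and mutation would act.  It always
runs the full G generations so generation counts are comparable.

## Benchmark metrics

G99 is the first generation whose best fitness *strictly* exceeds the 99th
percentile (linear interpolation) of the reference distribution; runs that
never cross are flagged rather than given a number, and aggregation reports
them separately.  Prend uses the weak percentile-rank convention (fraction of
reference values ≤ x), so a run that attains the enumerated maximum ranks at
exactly 100; strict and midrank conventions are available where duplicated
fitness values make the choice matter.  In the grid search, G99~ and Prend~
are min–max normalised per objective across every run in the grid, with
never-crossed runs mapped to the largest observed G99 first; S is averaged
per cell, the best cell per objective maximises mean S (ties to the
lexicographically smallest pair), and the cross-objective operating point is
the component-wise mean of the best pairs.  The shipped defaults
[p_C, p_M] = [0.9, 0.35] are that kind of averaged operating point.

## Numerical choices and limitations

Explicit Euler at dt = 0.01 h keeps per-step growth below ~1 % at realistic
rates; halving the step changes fixture endpoints by < 1 %.  The decay-only
closed form B₀e^(−δt) is matched to ~0.1 % at the default step.  Monod terms
with Km = 0 fall back to on/off uptake; zero-amount substrates contribute
nothing.  All randomness flows through numpy Generators seeded explicitly;
sub-seeds for multi-run studies derive from a SeedSequence and stay below
2³¹.

Out of scope by design: flux balance analysis and genome-scale networks,
spatial structure, pH/temperature effects, nitrogen/phosphorus bookkeeping,
multi-objective optimisation, and laboratory-automation interfaces.  The
evaluator callable is the extension point for all of these.
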