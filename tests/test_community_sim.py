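"""Consumer–resource simulator: kinetics, conservation, cross-feeding,
inoculum arithmetic, mapping generation and the growth-cessation rule."""

import numpy as np
import pytest

from envdesign import fixture as fx
from envdesign.community_sim import (
    Community,
    InoculumSpec,
    OrganismSpec,
    SimulationConfig,
    UptakeKinetics,
    carbon_balance,
    generate_mapping,
    generate_random_community,
    growth_stopped,
    inoculum_amounts,
    simulate_community,
)
from envdesign.env_space import (
    EnvironmentSpace,
    MediumSpec,
    Nutrient,
    NutrientPool,
    build_medium,
    random_environment,
)
from envdesign.io import community_to_dict


class TestInoculum:
    def test_od_bookkeeping_matches_hand_arithmetic(self):
        spec = InoculumSpec(od600=0.05, cells_at_od=1.6e7, cell_mass=2.8e-13, n_organisms=13)
        total, per_org = inoculum_amounts(spec)
        assert total == pytest.approx(4.48e-6, rel=1e-12)
        assert per_org == pytest.approx(3.446e-7, rel=1e-3)  # rounds to 3.45e-7

    def test_single_organism_gets_everything(self):
        spec = InoculumSpec(od600=0.05, cells_at_od=1.6e7, cell_mass=2.8e-13, n_organisms=1)
        total, per_org = inoculum_amounts(spec)
        assert per_org == total

    def test_zero_organisms_rejected(self):
        with pytest.raises(ValueError):
            InoculumSpec(od600=0.05, cells_at_od=1.6e7, cell_mass=2.8e-13, n_organisms=0)


class TestSimulatorBasics:
    def test_decay_only_matches_exponential_closed_form(self):
        org = OrganismSpec(id="a", uptake={}, yields={})
        cfg = SimulationConfig(
            duration=24, timestep=0.01, death_rate=0.1, inoculum_per_organism=1e-6
        )
        res = simulate_community([org], {}, cfg, carbon_atoms={})
        expect = 1e-6 * np.exp(-0.1 * 24)
        assert res.final_biomass[0] == pytest.approx(expect, rel=5e-3)  # Euler tolerance

    def test_no_death_no_consumables_state_exactly_constant(self):
        org = OrganismSpec(id="a", uptake={}, yields={})
        cfg = SimulationConfig(death_rate=0.0, inoculum_per_organism=1e-6)
        res = simulate_community([org], {"glc": 0.01}, cfg, carbon_atoms={"glc": 6})
        assert (res.biomass == 1e-6).all()
        assert (res.metabolites == 0.01).all()

    def test_final_biomass_bounded_by_mass_balance(self):
        # yield x nutrient amount is the ceiling; tight as Km -> 0 over a long run
        org = OrganismSpec(id="x", uptake={"glc": UptakeKinetics(10, 1e-4)}, yields={"glc": 0.15})
        cfg = SimulationConfig(death_rate=0.0, inoculum_per_organism=1e-7)
        res = simulate_community([org], {"glc": 0.003}, cfg, carbon_atoms={"glc": 6})
        ceiling = 1e-7 + 0.15 * 0.003
        assert res.final_biomass[0] <= ceiling + 1e-15
        assert res.final_biomass[0] == pytest.approx(ceiling, rel=1e-3)

    def test_cross_feeding_chain_and_auxotrophy_gate(self):
        A = OrganismSpec(
            id="A",
            uptake={"glc": UptakeKinetics(10, 0.05)},
            yields={"glc": 0.1},
            secretion={"glc": {"acetate": 0.3}},
        )
        B = OrganismSpec(
            id="B", uptake={"acetate": UptakeKinetics(10, 0.05)}, yields={"acetate": 0.04}
        )
        carbon = {"glc": 6, "acetate": 2}
        cfg = SimulationConfig(inoculum_per_organism=1e-7)
        res = simulate_community([A, B], {"glc": 0.003}, cfg, carbon_atoms=carbon)
        triples = {(r.donor, r.receiver, r.metabolite) for r in res.exchange_records}
        assert triples == {("A", "B", "acetate")}
        assert all(r.amount > 0 for r in res.exchange_records)
        # without the donor, B's only substrate never appears and B never grows
        alone = simulate_community([B], {"glc": 0.003}, cfg, carbon_atoms=carbon)
        assert (np.diff(alone.biomass[:, 0]) <= 0).all()

    def test_required_cofactor_gates_growth(self):
        aux = OrganismSpec(
            id="aux",
            uptake={"glc": UptakeKinetics(10, 0.05)},
            yields={"glc": 0.1},
            required_cofactors=frozenset({"thiamine"}),
        )
        carbon = {"glc": 6, "thiamine": 12}
        cfg = SimulationConfig(inoculum_per_organism=1e-7)
        gated = simulate_community([aux], {"glc": 0.003}, cfg, carbon_atoms=carbon)
        assert (np.diff(gated.biomass[:, 0]) <= 0).all()
        fed = simulate_community(
            [aux], {"glc": 0.003, "thiamine": 1e-6}, cfg, carbon_atoms=carbon
        )
        assert fed.final_biomass[0] > 1e-7

    def test_carbon_conserved_and_states_nonnegative_across_seeds(self):
        pool = fx.fixture_pool()
        space = fx.fixture_space()
        spec = fx.fixture_medium_spec()
        for seed in range(15):
            rng = np.random.default_rng(seed)
            com = generate_random_community(int(rng.integers(3, 7)), pool, rng=rng)
            env = random_environment(space, rng)
            carbon = {**pool.carbon_atoms(), **com.metabolite_carbon}
            res = simulate_community(
                com.organisms,
                build_medium(env, spec, pool),
                SimulationConfig(duration=12, timestep=0.02),
                carbon_atoms=carbon,
            )
            start, end = carbon_balance(res, carbon)
            assert end == pytest.approx(start, rel=1e-6)
            assert res.respired_carbon_mmol == pytest.approx(0.0, abs=1e-12)
            assert res.biomass.min() >= 0
            assert res.metabolites.min() >= 0

    def test_halving_the_timestep_changes_little(self, community, pool):
        from envdesign.env_space import Environment

        env = Environment.from_ids(["glc", "ala", "xyl"])
        medium = build_medium(env, fx.fixture_medium_spec(), pool)
        carbon = {**pool.carbon_atoms(), **community.metabolite_carbon}
        base = fx.fixture_simulation_config()
        fine = SimulationConfig(
            duration=24,
            timestep=0.005,
            death_rate=0.1,
            inoculum_per_organism=base.inoculum_per_organism,
        )
        r1 = simulate_community(community.organisms, medium, base, carbon_atoms=carbon)
        r2 = simulate_community(community.organisms, medium, fine, carbon_atoms=carbon)
        rel = np.abs(r1.final_biomass - r2.final_biomass) / np.maximum(
            r1.final_biomass, 1e-12
        )
        assert rel.max() < 0.01

    def test_unresolved_substrate_rejected(self):
        org = OrganismSpec(id="a", uptake={"mystery": UptakeKinetics(1, 0.1)}, yields={})
        with pytest.raises(KeyError, match="mystery"):
            simulate_community([org], {}, SimulationConfig(), carbon_atoms={})


class TestGrowthStopped:
    def test_rise_then_plateau_counts_as_stopped(self):
        traj = np.concatenate([np.linspace(1, 2, 50), np.full(50, 2.0)])
        assert growth_stopped(traj)

    def test_still_increasing_at_end_not_stopped(self):
        assert not growth_stopped(np.linspace(1, 2, 100))

    def test_never_grew_is_not_stopped_under_literal_rule(self):
        assert not growth_stopped(np.linspace(1, 0.5, 100))

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            growth_stopped([1.0])


class TestGenerateRandomCommunity:
    pool = fx.fixture_pool()

    def test_seeded_generation_reproducible(self):
        a = generate_random_community(8, self.pool, rng=np.random.default_rng(5))
        b = generate_random_community(8, self.pool, rng=np.random.default_rng(5))
        assert community_to_dict(a) == community_to_dict(b)

    def test_all_specialist_mix_never_consumes_byproducts(self):
        com = generate_random_community(
            6,
            self.pool,
            archetype_mix={"specialist": 1.0},
            rng=np.random.default_rng(2),
        )
        byproducts = set(com.metabolite_carbon)
        for o in com.organisms:
            assert not byproducts & set(o.uptake)
            assert not o.required_cofactors

    def test_every_auxotroph_cofactor_is_secretable_by_another_organism(self):
        for seed in range(10):
            com = generate_random_community(
                10, self.pool, rng=np.random.default_rng(seed)
            )
            for o in com.organisms:
                for cof in o.required_cofactors:
                    suppliers = [
                        other
                        for other in com.organisms
                        if other.id != o.id
                        and any(cof in fr for fr in other.secretion.values())
                    ]
                    assert suppliers, f"seed {seed}: no supplier for {cof}"

    def test_secretion_fractions_within_unit_interval(self):
        com = generate_random_community(13, self.pool, rng=np.random.default_rng(9))
        for o in com.organisms:
            for fr in o.secretion.values():
                assert 0 <= sum(fr.values()) <= 1


class TestMapping:
    def test_two_nutrient_power_set_has_four_rows(self):
        pool = NutrientPool((Nutrient("a", "a", 6), Nutrient("b", "b", 3)))
        org = OrganismSpec(
            id="x", uptake={"a": UptakeKinetics(10, 0.05)}, yields={"a": 0.1}
        )
        com = Community(organisms=(org,), metabolite_carbon={})
        space = EnvironmentSpace(pool, 2, include_empty=True)
        mapping = generate_mapping(
            com, space, MediumSpec(), SimulationConfig(duration=2, timestep=0.02)
        )
        assert len(mapping) == 4
        assert [e.sorted_ids for e in mapping.environments()][0] == ()

    def test_packaged_fixture_maps_all_176_environments(self, mapping):
        # sum over k=0..3 of C(10, k)
        from math import comb

        assert len(mapping) == sum(comb(10, k) for k in range(4))

    def test_mapping_regeneration_is_deterministic(self):
        pool = NutrientPool((Nutrient("a", "a", 6), Nutrient("b", "b", 3)))
        com = generate_random_community(3, pool, rng=np.random.default_rng(1))
        space = EnvironmentSpace(pool, 2, include_empty=True)
        cfg = SimulationConfig(duration=4, timestep=0.02)
        m1 = generate_mapping(com, space, MediumSpec(), cfg)
        m2 = generate_mapping(com, space, MediumSpec(), cfg)
        assert [s for _, s in m1.entries] == [s for _, s in m2.entries]

    def test_fixture_satisfies_its_structural_contract(self, mapping):
        checks = fx.validate_fixture(mapping)
        assert all(checks.values()), checks
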