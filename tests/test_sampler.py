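"""Monte Carlo machinery: moves, Metropolis rule, exchange, WTE, ensembles."""

import dataclasses

import numpy as np
import pytest

from conftest import c2_transform
from xlmodel._engine import ScoringEngine
from xlmodel.io import CrossLinkRecord
from xlmodel.representation import (
    AssemblyTopology,
    Box,
    build_assembly,
)
from xlmodel.restraints import RestraintSet
from xlmodel.sampler import (
    Ensemble,
    ModelState,
    SamplerConfig,
    Snapshot,
    WTEBias,
    initialize_state,
    mc_step,
    metropolis_accept,
    replica_exchange_sweep,
    run_sampling,
    temperature_ladder,
)


@pytest.fixture
def boxed_topology():
    return AssemblyTopology(
        sequences={"A": "A" * 30, "B": "A" * 20},
        copy_count=2,
        symmetry=c2_transform(80.0),
        bounding_boxes={"A": Box([0, 0, 0], [10, 10, 10])},
    )


class TestTemperatureLadder:
    def test_geometric_spacing(self):
        temps = temperature_ladder(1.0, 3.0, 34)
        assert temps[0] == pytest.approx(1.0)
        assert temps[-1] == pytest.approx(3.0)
        ratios = temps[1:] / temps[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_single_replica(self):
        assert temperature_ladder(1.0, 3.0, 1).tolist() == [1.0]


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-0.5, 1.0, rng) for _ in range(100))
        assert all(metropolis_accept(0.0, 1.0, rng) for _ in range(100))

    def test_requires_positive_temperature(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)


class TestInitializeState:
    def test_boxed_component_inside_its_box(self, boxed_topology, rng):
        state = initialize_state(boxed_topology, rng)
        assembly = build_assembly(boxed_topology)
        sl = assembly.chain_slice("A", 0)
        box = boxed_topology.bounding_boxes["A"]
        assert box.contains(state.coords[sl]).all()

    def test_deterministic_given_seed(self, boxed_topology):
        s1 = initialize_state(boxed_topology, np.random.default_rng(5))
        s2 = initialize_state(boxed_topology, np.random.default_rng(5))
        assert np.array_equal(s1.coords, s2.coords)

    def test_unboxed_beads_fall_in_union_of_boxes(self):
        topology = AssemblyTopology(
            sequences={"A": "A" * 10, "B": "A" * 10, "C": "A" * 10},
            copy_count=1,
            bounding_boxes={
                "A": Box([0, 0, 0], [10, 10, 10]),
                "C": Box([50, 0, 0], [60, 10, 10]),
            },
        )
        assembly = build_assembly(topology)
        sl = assembly.chain_slice("B", 0)
        boxes = list(topology.bounding_boxes.values())
        for seed in range(1000):
            state = initialize_state(
                topology, np.random.default_rng(seed), assembly=assembly
            )
            pt = state.coords[sl]
            assert any(b.contains(pt).all() for b in boxes)

    def test_no_boxes_is_an_error(self):
        topology = AssemblyTopology(sequences={"A": "A" * 10}, copy_count=1)
        with pytest.raises(ValueError):
            initialize_state(topology, np.random.default_rng(0))

    def test_symmetry_applied(self, boxed_topology, rng):
        state = initialize_state(boxed_topology, rng)
        assembly = build_assembly(boxed_topology)
        n0 = assembly.n_per_copy
        expected = boxed_topology.symmetry.apply(state.coords[:n0])
        assert np.allclose(state.coords[n0:], expected)


class TestMcStep:
    @pytest.fixture
    def engine(self, boxed_topology):
        restraints = RestraintSet(
            crosslinks=[CrossLinkRecord("A", 5, "B", 5, 0.001)]
        )
        return ScoringEngine(build_assembly(boxed_topology), restraints)

    def test_energy_cache_consistent(self, engine, boxed_topology, rng):
        state = initialize_state(boxed_topology, rng, engine=engine)
        for _ in range(50):
            state, _ = mc_step(engine, state, 1.0, rng)
            assert state.energy == pytest.approx(
                engine.full_energy(state.coords), rel=1e-9, abs=1e-9
            )

    def test_rejected_move_leaves_coords_unchanged(self, engine, boxed_topology, rng):
        state = initialize_state(boxed_topology, rng, engine=engine)
        # near-zero temperature makes uphill moves essentially impossible
        seen_reject = False
        for _ in range(200):
            before = state.coords.copy()
            state, accepted = mc_step(engine, state, 1e-9, rng)
            if not accepted:
                seen_reject = True
                assert np.array_equal(state.coords, before)
        assert seen_reject

    def test_symmetry_maintained_through_sampling(self, engine, boxed_topology, rng):
        state = initialize_state(boxed_topology, rng, engine=engine)
        res = engine.run(state.coords, 1.5, 2000, rng, energy=state.energy)
        n0 = engine.n_per_copy
        expected = boxed_topology.symmetry.apply(state.coords[:n0])
        assert np.allclose(state.coords[n0:], expected, atol=1e-10)
        assert res.n_accepted > 0


class TestReplicaExchange:
    def test_equal_energies_always_swap(self, rng):
        states = [ModelState(np.zeros((1, 3)), 5.0) for _ in range(4)]
        temps = np.array([1.0, 1.5, 2.2, 3.0])
        ids = [id(s) for s in states]
        accepted = replica_exchange_sweep(states, temps, rng, sweep_index=0)
        assert accepted == 2
        assert [id(s) for s in states] == [ids[1], ids[0], ids[3], ids[2]]

    def test_equal_temperatures_always_swap(self, rng):
        states = [ModelState(np.zeros((1, 3)), e) for e in (1.0, 50.0)]
        assert replica_exchange_sweep(states, np.array([2.0, 2.0]), rng) == 1

    def test_alternating_pairing(self, rng):
        states = [ModelState(np.zeros((1, 3)), 0.0) for _ in range(4)]
        temps = np.array([1.0, 1.5, 2.2, 3.0])
        ids = [id(s) for s in states]
        replica_exchange_sweep(states, temps, rng, sweep_index=1)
        # odd sweep pairs (1,2) only
        assert [id(s) for s in states] == [ids[0], ids[2], ids[1], ids[3]]


class TestWTE:
    def test_zero_deposits_zero_bias(self):
        bias = WTEBias(gamma=16, sigma=2.0, height=1.0, temperature=1.0)
        assert bias.value(3.7) == 0.0

    def test_first_deposit_height(self):
        bias = WTEBias(gamma=16, sigma=2.0, height=1.0, temperature=1.0)
        bias.deposit(10.0)
        assert bias.value(10.0) == pytest.approx(1.0)

    def test_heights_decay_at_revisited_energy(self):
        bias = WTEBias(gamma=16, sigma=2.0, height=1.0, temperature=1.0)
        heights = [bias.deposit(0.0) for _ in range(5)]
        assert all(a > b for a, b in zip(heights, heights[1:]))

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError):
            WTEBias(gamma=1.0, sigma=2.0, height=1.0, temperature=1.0)
        with pytest.raises(ValueError):
            SamplerConfig(wte_enabled=True, wte_gamma=0.5)


class TestRunSampling:
    @pytest.fixture
    def problem(self, boxed_topology):
        restraints = RestraintSet(
            crosslinks=[CrossLinkRecord("A", 5, "B", 15, 0.001)]
        )
        return boxed_topology, restraints

    def test_zero_steps_returns_initial_state(self, problem):
        topology, restraints = problem
        config = SamplerConfig(n_replicas=2, n_steps=0, seed=3, top_n_keep=10)
        ensemble = run_sampling(topology, restraints, config)
        assert len(ensemble) == 1

    def test_scores_sorted_and_capped(self, problem):
        topology, restraints = problem
        config = SamplerConfig(n_replicas=2, n_steps=5000, seed=3, top_n_keep=5)
        ensemble = run_sampling(topology, restraints, config)
        assert len(ensemble) <= 5
        scores = ensemble.scores
        assert (np.diff(scores) >= 0).all()

    def test_bitwise_reproducible(self, problem):
        topology, restraints = problem
        config = SamplerConfig(n_replicas=3, n_steps=4000, seed=11, top_n_keep=8)
        e1 = run_sampling(topology, restraints, config)
        e2 = run_sampling(topology, restraints, config)
        assert np.array_equal(e1.coords_stack(), e2.coords_stack())
        assert np.array_equal(e1.scores, e2.scores)

    def test_feasible_restraints_reach_zero(self):
        # 3-bead chain with one cross-link: every restraint is satisfiable
        topology = AssemblyTopology(sequences={"A": "A" * 30}, copy_count=1)
        restraints = RestraintSet(
            crosslinks=[CrossLinkRecord("A", 5, "A", 25, 0.001)]
        )
        assembly = build_assembly(topology)
        engine = ScoringEngine(assembly, restraints)
        rng = np.random.default_rng(2)
        init = ModelState(rng.normal(scale=30.0, size=(3, 3)))
        config = SamplerConfig(
            n_replicas=2, n_steps=100_000, seed=2, top_n_keep=10, t_min=0.2
        )
        ensemble = run_sampling(
            topology, restraints, config, engine=engine,
            initial_states=[ModelState(init.coords.copy()), ModelState(init.coords.copy())],
        )
        assert ensemble.best.score < 1e-3

    def test_wte_smoke(self, problem):
        topology, restraints = problem
        config = SamplerConfig(
            n_replicas=2, n_steps=3000, seed=5, top_n_keep=5, wte_enabled=True
        )
        ensemble = run_sampling(topology, restraints, config)
        assert len(ensemble) >= 1


class TestEnsemble:
    def test_sorted_on_construction(self):
        snaps = [
            Snapshot(score=s, step=0, replica=0, coords=np.zeros((1, 3)))
            for s in (3.0, 1.0, 2.0)
        ]
        ens = Ensemble(models=snaps)
        assert ens.scores.tolist() == [1.0, 2.0, 3.0]
        assert ens.best.score == 1.0
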