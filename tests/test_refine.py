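"""Monte-Carlo rigid-body refinement: moves, loop invariants, recovery."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import saxskit as sk
from saxskit.refine import (
    MCConfig,
    RigidBodyModel,
    interface_pairs,
    mc_refine,
    propose_move,
)
from saxskit.scatter import chi_fit, debye_profile
from saxskit.structures import (
    RigidBodyAssembly,
    RigidTransform,
    StructureError,
    apply_assembly,
    min_intercomponent_distance,
)


@pytest.fixture(scope="module")
def noisy_data():
    assembly = sk.make_two_lobe_dimer(lobe_radius=8.0, separation=20.0,
                                      n_beads_per_lobe=60, seed=11)
    curve = sk.simulate_curve(apply_assembly(assembly),
                              noise=sk.NoiseModel(0.02, 0.0, seed=5))
    return assembly, curve


class TestProposeMove:
    def test_zero_amplitudes_leave_assembly_unchanged(self, two_component_assembly):
        cfg = MCConfig(max_rotation=0.0, max_translation=0.0)
        rng = np.random.default_rng(0)
        prop = propose_move(two_component_assembly, cfg, rng)
        for cid in prop.component_ids:
            t0 = two_component_assembly.transforms[cid]
            t1 = prop.transforms[cid]
            np.testing.assert_allclose(t1.rotation, t0.rotation, atol=1e-12)
            np.testing.assert_allclose(t1.translation, t0.translation, atol=1e-12)

    def test_rotations_stay_orthonormal_over_many_proposals(self, two_component_assembly):
        cfg = MCConfig(max_rotation=30.0, max_translation=3.0)
        rng = np.random.default_rng(1)
        a = two_component_assembly
        for _ in range(1000):
            a = propose_move(a, cfg, rng)
        rot = a.transforms["B"].rotation
        assert np.abs(rot.T @ rot - np.eye(3)).max() < 1e-9
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_translation_amplitude_order_statistics(self, two_component_assembly):
        cfg = MCConfig(max_rotation=1.0, max_translation=2.0)
        rng = np.random.default_rng(2)
        comps = []
        for _ in range(2000):
            prop = propose_move(two_component_assembly, cfg, rng)
            delta = (prop.transforms["B"].translation
                     - two_component_assembly.transforms["B"].translation)
            comps.extend(np.abs(delta))
        observed_max = max(comps)
        # max of 6000 Uniform(0, mt) draws lands in the top 5% band
        assert 0.95 * cfg.max_translation <= observed_max <= cfg.max_translation

    def test_only_movable_components_change(self, two_component_assembly):
        cfg = MCConfig(max_rotation=10.0, max_translation=2.0)
        rng = np.random.default_rng(3)
        prop = propose_move(two_component_assembly, cfg, rng)
        np.testing.assert_array_equal(prop.transforms["A"].rotation, np.eye(3))

    def test_no_movable_components_is_an_error(self, small_sphere):
        asm = RigidBodyAssembly({"A": small_sphere})
        with pytest.raises(StructureError):
            propose_move(asm, MCConfig(), np.random.default_rng(0))


class TestRefinementLoop:
    def test_zero_steps_returns_starting_chi(self, noisy_data):
        assembly, curve = noisy_data
        res = mc_refine(assembly, curve, MCConfig(n_steps=0))
        assert res.trace == ()
        assert res.best_chi == pytest.approx(res.start_chi, rel=1e-3)
        for cid in assembly.component_ids:
            np.testing.assert_array_equal(
                res.best_assembly.transforms[cid].rotation,
                assembly.transforms[cid].rotation)

    def test_identical_seeds_give_bit_identical_runs(self, noisy_data):
        assembly, curve = noisy_data
        cfg = MCConfig(n_steps=150, seed=9)
        r1 = mc_refine(assembly, curve, cfg)
        r2 = mc_refine(assembly, curve, cfg)
        assert r1.trace == r2.trace
        assert r1.best_chi == r2.best_chi
        for cid in assembly.component_ids:
            np.testing.assert_array_equal(
                r1.best_assembly.transforms[cid].rotation,
                r2.best_assembly.transforms[cid].rotation)
            np.testing.assert_array_equal(
                r1.best_assembly.transforms[cid].translation,
                r2.best_assembly.transforms[cid].translation)

    def test_trace_bookkeeping(self, noisy_data):
        assembly, curve = noisy_data
        cfg = MCConfig(n_steps=200, seed=4, max_translation=1.0)
        res = mc_refine(assembly, curve, cfg)
        assert len(res.trace) == 200
        assert res.n_accepted == sum(t.accepted for t in res.trace)
        assert res.n_clashed == sum(t.clash for t in res.trace)
        # clash-flagged proposals are never accepted and carry no chi
        for t in res.trace:
            if t.clash:
                assert not t.accepted and math.isnan(t.proposed_chi)

    def test_best_chi_is_minimum_over_accepted_proposals(self, noisy_data):
        assembly, curve = noisy_data
        res = mc_refine(assembly, curve, MCConfig(n_steps=300, seed=6))
        accepted = [t.proposed_chi for t in res.trace if t.accepted]
        if accepted:
            assert res.best_chi == pytest.approx(min(min(accepted), res.start_chi))

    def test_greedy_acceptance_never_increases_current_chi(self, noisy_data):
        assembly, curve = noisy_data
        res = mc_refine(assembly, curve,
                        MCConfig(n_steps=300, seed=8, temperature=0.0,
                                 restart_interval=0))
        current = None
        for t in res.trace:
            if t.accepted:
                if current is not None:
                    assert t.proposed_chi <= current + 1e-12
                current = t.proposed_chi

    def test_accepted_states_respect_clash_threshold(self):
        # threshold set just below the starting gap so the walk produces
        # genuine clash rejections
        a = sk.make_bead_sphere(6.0, 40, seed=1, component_id="A")
        b = sk.make_bead_sphere(6.0, 40, seed=2, component_id="B")
        b = b.with_coords(b.coords + np.array([16.0, 0.0, 0.0]))
        assembly = RigidBodyAssembly({"A": a, "B": b})
        threshold = min_intercomponent_distance(assembly) - 0.4
        curve = sk.simulate_curve(apply_assembly(assembly),
                                  noise=sk.NoiseModel(0.02, 0.0, seed=1))
        cfg = MCConfig(n_steps=400, seed=2, max_translation=1.5,
                       clash_threshold=threshold)
        res = mc_refine(assembly, curve, cfg)
        assert res.n_clashed > 0  # the test only bites if clashes happened
        assert min_intercomponent_distance(res.best_assembly) >= threshold

    def test_metropolis_temperature_accepts_some_uphill_moves(self, noisy_data):
        assembly, curve = noisy_data
        greedy = mc_refine(assembly, curve,
                           MCConfig(n_steps=150, seed=14, temperature=0.0))
        warm = mc_refine(assembly, curve,
                         MCConfig(n_steps=150, seed=14, temperature=2.0,
                                  anneal=0.995))
        assert warm.n_accepted >= greedy.n_accepted
        assert len(warm.trace) == 150

    def test_optional_move_schedules_run_and_stay_deterministic(self, noisy_data):
        assembly, curve = noisy_data
        cfg = MCConfig(n_steps=80, seed=12, multiscale=True, orbit_fraction=0.5)
        r1 = mc_refine(assembly, curve, cfg)
        r2 = mc_refine(assembly, curve, cfg)
        assert r1.trace == r2.trace
        rot = r1.best_assembly.transforms["B"].rotation
        assert np.abs(rot.T @ rot - np.eye(3)).max() < 1e-9

    def test_single_component_assembly_refused(self, small_sphere, q_grid):
        asm = RigidBodyAssembly({"A": small_sphere})
        curve = sk.simulate_curve(small_sphere, noise=sk.NoiseModel(0.02, 0.0, 1))
        with pytest.raises(StructureError):
            RigidBodyModel(asm, curve)

    def test_translation_only_toy_reaches_grid_search_optimum(self):
        a = sk.make_bead_sphere(8.0, 60, seed=1, component_id="A")
        b = sk.make_bead_sphere(8.0, 60, seed=2, component_id="B")
        b = b.with_coords(b.coords + np.array([25.0, 0.0, 0.0]))
        truth = RigidBodyAssembly({"A": a, "B": b})
        curve = sk.simulate_curve(apply_assembly(truth),
                                  noise=sk.NoiseModel(0.02, 0.0, 7))
        start = truth.replace_transform(
            "B", RigidTransform(np.eye(3), np.array([-6.0, 0.0, 0.0])))
        res = mc_refine(start, curve,
                        MCConfig(n_steps=600, seed=1, max_rotation=0.0,
                                 max_translation=1.0))
        # exhaustive 1-D grid over the separation axis (the only strong mode)
        grid_chis = []
        for dx in np.arange(-8.0, 8.001, 0.1):
            asm = truth.replace_transform(
                "B", RigidTransform(np.eye(3), np.array([dx, 0.0, 0.0])))
            grid_chis.append(
                chi_fit(debye_profile(apply_assembly(asm), curve.q), curve).chi)
        assert res.best_chi <= 1.10 * min(grid_chis)


class TestInterfacePairs:
    def test_far_apart_components_have_no_contacts(self, two_component_assembly):
        assert interface_pairs(two_component_assembly, cutoff=1.0) == []

    def test_single_contact_pair(self):
        a = sk.Structure.from_arrays([[0.0, 0.0, 0.0]], component_id="A")
        b = sk.Structure.from_arrays([[3.0, 0.0, 0.0], [40.0, 0.0, 0.0]],
                                     component_id="B")
        asm = RigidBodyAssembly({"A": a, "B": b})
        pairs = interface_pairs(asm, cutoff=5.0)
        assert len(pairs) == 1
        assert pairs[0].distance == pytest.approx(3.0)

    def test_matches_brute_force_filter(self, two_component_assembly):
        cutoff = 6.0
        pairs = interface_pairs(two_component_assembly, cutoff)
        xa = two_component_assembly.transformed_coords("A")
        xb = two_component_assembly.transformed_coords("B")
        expected = int((cdist(xa, xb) <= cutoff).sum())
        assert len(pairs) == expected
        dists = [p.distance for p in pairs]
        assert dists == sorted(dists)
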