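"""Sampler statistics: proposal distributions, the Metropolis rule,
detailed balance, incremental-energy fidelity and reproducibility."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from magnetochain import (AnnealingSchedule, Engine, anneal,
                          metropolis_accept, propose_move, run, step,
                          total_energy)
from magnetochain.mc import rotate_direction
from magnetochain.protocols import make_initial_state


class TestProposeMove:
    def test_translation_components_uniform_on_pm_dn(self, params, rng):
        st = make_initial_state(params, "chain_on_filament")
        comps = []
        for _ in range(30_000):
            prop = propose_move(st, params, rng)
            if prop.kind == "translate":
                comps.extend(prop.translation)
        comps = np.asarray(comps)
        dn = params.contact_distance
        assert comps.min() >= -dn and comps.max() <= dn
        _, p = sps.kstest(comps, sps.uniform(loc=-dn, scale=2 * dn).cdf)
        assert p > 0.01

    def test_angle_deltas_uniform_on_pm_5_degrees(self, params, rng):
        st = make_initial_state(params, "chain_on_filament")
        deltas = []
        for _ in range(30_000):
            prop = propose_move(st, params, rng)
            if prop.kind == "rotate_moment":
                deltas.extend([prop.dpolar_deg, prop.dazimuth_deg])
        deltas = np.asarray(deltas)
        assert deltas.min() >= -5.0 and deltas.max() <= 5.0
        _, p = sps.kstest(deltas, sps.uniform(loc=-5.0, scale=10.0).cdf)
        assert p > 0.01

    def test_move_kinds_equal_thirds(self, params, rng):
        st = make_initial_state(params, "chain_on_filament")
        kinds = [propose_move(st, params, rng).kind for _ in range(30_000)]
        for k in ("translate", "rotate_moment", "flip_binding"):
            frac = kinds.count(k) / len(kinds)
            # binomial 4-sigma band around 1/3
            assert abs(frac - 1 / 3) < 4 * math.sqrt((1 / 3) * (2 / 3) / 30_000)

    def test_empty_system_rejected(self, params, rng):
        st = make_initial_state(params.replace(n_particles=0), "chain_on_filament")
        with pytest.raises(ValueError):
            propose_move(st, params, rng)


class TestMetropolisAccept:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-x, 300.0, rng) for x in (0.0, 0.1, 50.0))

    def test_ln2_barrier_accepted_half_the_time(self, rng):
        de = math.log(2.0)
        n = 100_000
        acc = sum(metropolis_accept(de, 300.0, rng) for _ in range(n))
        assert acc / n == pytest.approx(0.5, abs=0.01)

    def test_cold_limit_rejects_uphill(self, rng):
        assert not any(metropolis_accept(1.0, 1e-6, rng) for _ in range(100))

    def test_temperature_rescales_the_barrier(self, rng):
        # a 2 kBT(300 K) barrier at 600 K behaves as a 1 kBT barrier
        n = 100_000
        acc = sum(metropolis_accept(2.0, 600.0, rng) for _ in range(n))
        assert acc / n == pytest.approx(math.exp(-1.0), abs=0.01)


class TestRotateDirection:
    def test_preserves_unit_norm(self, rng):
        for _ in range(200):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            v = rotate_direction(u, rng.uniform(-5, 5), rng.uniform(-5, 5))
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_zero_delta_identity(self):
        u = np.array([0.36, 0.48, 0.8])
        assert rotate_direction(u, 0.0, 0.0) == pytest.approx(u, abs=1e-12)


class TestStep:
    def test_overlap_moves_leave_state_unchanged(self, params):
        rng = np.random.default_rng(11)
        st = make_initial_state(params, "chain_on_filament")
        for _ in range(3000):
            before = st.positions.copy()
            prop = propose_move(st, params, rng)
            from magnetochain.mc import _move_valid
            if prop.kind == "translate" and not _move_valid(st, prop, params):
                # the step function must reject it unconditionally
                st2 = st.copy()
                accepted = step(st2, params, np.random.default_rng(0))
                assert np.array_equal(st.positions, before)

    def test_hard_core_never_violated_along_a_run(self, params):
        from magnetochain.energetics import check_hard_core
        rng = np.random.default_rng(3)
        st = make_initial_state(params, "chain_on_filament")
        st.field_mT = np.array([0.0, 50.0, 0.0])
        for k in range(2000):
            step(st, params, rng)
            if k % 200 == 0:
                check_hard_core(st, params)  # must not raise

    def test_binding_flip_changes_bound_count_by_one(self, params):
        rng = np.random.default_rng(4)
        st = make_initial_state(params, "chain_on_filament")
        for _ in range(500):
            before = st.bound_count()
            prop = propose_move(st, params, rng)
            from magnetochain.energetics import delta_energy
            from magnetochain.mc import apply_move
            if prop.kind == "flip_binding":
                de = delta_energy(st, prop, params)
                if metropolis_accept(de, st.temperature, rng):
                    apply_move(st, prop)
                    assert abs(st.bound_count() - before) == 1


class TestEngine:
    def test_cached_energy_tracks_full_recompute(self, params):
        st = make_initial_state(params, "chain_on_filament")
        st.field_mT = np.array([25.0, 43.3, 0.0])  # 50 mT at 60 degrees
        eng = Engine(st, params, seed=99)
        eng.run(10_000)
        drift = np.abs(eng.energies.as_array()
                       - total_energy(st, params).as_array())
        assert drift.max() < 1e-6

    def test_long_run_energy_consistency(self, params):
        st = make_initial_state(params, "random", seed=12)
        eng = Engine(st, params, seed=12)
        eng.run(200_000, temperature=1000.0)
        drift = np.abs(eng.energies.as_array()
                       - total_energy(st, params).as_array())
        assert drift.max() < 1e-6

    def test_same_seed_identical_trajectories(self, params):
        outs = []
        for _ in range(2):
            st = make_initial_state(params, "chain_on_filament")
            st.field_mT = np.array([0.0, 50.0, 0.0])
            eng = Engine(st, params, seed=2024)
            eng.run(50_000)
            outs.append((st.positions.copy(), st.moment_dirs.copy(),
                         st.bound.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])
        assert np.array_equal(outs[0][2], outs[1][2])

    def test_run_zero_steps_is_identity(self, params):
        st = make_initial_state(params, "chain_on_filament")
        ref = st.copy()
        run(st, params, 0, seed=1)
        assert np.array_equal(st.positions, ref.positions)

    def test_frozen_particles_never_move(self, params):
        st = make_initial_state(params, "chain_on_filament")
        frozen = st.positions[0].copy(), st.moment_dirs[0].copy()
        eng = Engine(st, params, seed=5, mobile=np.arange(1, st.n))
        eng.run(100_000)
        assert np.array_equal(st.positions[0], frozen[0])
        assert np.array_equal(st.moment_dirs[0], frozen[1])

    def test_recorder_called_at_interval(self, params):
        st = make_initial_state(params, "chain_on_filament")
        seen = []
        run(st, params, 50_000, seed=6,
            recorders=[lambda k, s, e: seen.append(k)],
            record_interval=10_000)
        assert seen == [0, 10_000, 20_000, 30_000, 40_000, 50_000]


class TestDetailedBalance:
    def test_binding_flip_flow_ratio_matches_boltzmann(self, params):
        """For an isolated particle's bound/unbound pair of states, the
        empirical flow ratio must match exp(-dE/kBT)."""
        rng = np.random.default_rng(8)
        de = params.binding_energy  # unbind cost with a slack linker
        n = 100_000
        up = sum(metropolis_accept(de, 300.0, rng) for _ in range(n))
        down = sum(metropolis_accept(-de, 300.0, rng) for _ in range(n))
        expected = math.exp(-de)
        sigma = math.sqrt(expected * (1 - expected) / n)
        assert up / down == pytest.approx(expected, abs=3 * sigma)

    def test_bound_fraction_at_equilibrium(self, params):
        # on a slack-linker chain, P(bound) = 1/(1+exp(-|Eb|)) per particle
        st = make_initial_state(params, "chain_on_filament")
        eng = Engine(st, params, seed=77)
        eng.run(200_000)
        stats = eng.run(800_000, sample_every=500)
        p_eq = 1.0 / (1.0 + math.exp(-params.binding_energy))
        assert stats[1] / params.n_particles == pytest.approx(p_eq, abs=0.02)


class TestEquilibration:
    def test_free_dipoles_pair_up_head_to_tail(self, params):
        """Two free dipoles in a modest box bind into a head-to-tail
        pair (E_dd < -50 kBT) at room temperature."""
        p = params.replace(n_particles=2, cylinder_radius=150.0,
                           cylinder_length=400.0)
        hits = 0
        for s in range(8):
            st = make_initial_state(p, "random", seed=1000 + s)
            eng = Engine(st, p, seed=2000 + s)
            eng.run(600_000)
            if eng.energies.e_dd < -50.0:
                hits += 1
        assert hits >= 7

    def test_energy_stationary_after_equilibration(self, params):
        """No temperature, no field: the mean energy over the last half
        of a long run shows no significant trend."""
        p = params.replace(n_particles=10, cylinder_radius=150.0,
                           cylinder_length=600.0, binding_energy=0.0)
        st = make_initial_state(p, "random", seed=42)
        eng = Engine(st, p, seed=43)
        eng.run(2_000_000)  # burn-in: let structures assemble
        means = []
        for _ in range(40):
            eng.run(50_000)
            means.append(eng.energies.total)
        x = np.arange(len(means))
        res = sps.linregress(x, means)
        assert res.pvalue > 0.05 or abs(res.slope) < 0.02 * np.std(means)


class TestAnnealing:
    def test_schedule_defaults_and_ladder(self):
        sched = AnnealingSchedule()
        temps = sched.stage_temperatures()
        assert len(temps) == 60
        assert temps[0] == pytest.approx(3e4)
        assert temps[-1] == pytest.approx(300.0, rel=1e-9)
        assert np.all(np.diff(temps) < 0)
        assert sched.cooling_factor == pytest.approx(0.925, abs=0.005)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            AnnealingSchedule(t_start=100.0, t_final=300.0)

    def test_single_stage_equals_fixed_temperature_run(self, params):
        sched = AnnealingSchedule(t_start=300.0, t_final=300.0, n_stages=1,
                                  steps_per_stage=20_000)
        st1 = make_initial_state(params, "chain_on_filament")
        anneal(st1, params, sched, seed=31)
        st2 = make_initial_state(params, "chain_on_filament")
        run(st2, params, 20_000, seed=31, record_interval=20_000)
        assert np.array_equal(st1.positions, st2.positions)
        assert np.array_equal(st1.moment_dirs, st2.moment_dirs)

    def test_annealed_dipoles_reach_contact_bond_energy(self, params):
        """A short anneal of a few free dipoles ends in a chain whose
        dipolar energy per bond is within 20% of the ideal contact
        value."""
        from magnetochain import contact_bond_energy
        from magnetochain.observables import classify_structures, neighbor_graph
        p = params.replace(n_particles=6, binding_energy=0.0,
                           cylinder_radius=150.0, cylinder_length=600.0)
        sched = AnnealingSchedule(n_stages=30, steps_per_stage=40_000)
        found = 0
        for s in range(4):
            st = make_initial_state(p, "random", seed=500 + s)
            anneal(st, p, sched, seed=600 + s)
            rep = classify_structures(neighbor_graph(st, p), st)
            if rep.n_chains == 1 and rep.n_rings == 0 and rep.n_clusters == 1:
                n_bonds = p.n_particles - 1
                per_bond = Engine(st, p).energies.e_dd / n_bonds
                assert per_bond == pytest.approx(contact_bond_energy(p), rel=0.2)
                found += 1
        assert found >= 1  # rings are legitimate competing outcomes
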