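import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hyp_st
from scipy import stats

from dmdrex import engine
from dmdrex.engine import SystemState, andersen_kick, predict_pair_event, resolve_collision
from dmdrex.models import build_mini_bundle
from dmdrex.potentials import InteractionModel, StepPotential
from dmdrex.topology import ChainTopology


def two_bead_state(r_i, v_i, r_j=(0, 0, 0), v_j=(0, 0, 0), mass=1.0):
    return SystemState(
        positions=np.array([r_i, r_j], dtype=float),
        velocities=np.array([v_i, v_j], dtype=float),
        masses=np.array([mass, mass]),
    )


class TestPredict:
    def test_head_on_linear_motion(self):
        st = two_bead_state((10, 0, 0), (-1, 0, 0))
        ev = predict_pair_event(st, (0, 1), StepPotential.hard_core(4.0))
        assert ev.time == pytest.approx(6.0)
        assert ev.direction == -1

    def test_perpendicular_motion_crosses_outer_boundary(self):
        # boundaries at 4 and 12, start at 10: |r+vt| = 12 at t = √44
        st = two_bead_state((10, 0, 0), (0, 1, 0))
        pot = StepPotential((4.0, 12.0), (math.inf, -1.0, 0.0))
        ev = predict_pair_event(st, (0, 1), pot)
        assert ev.direction == 1
        assert ev.time == pytest.approx(math.sqrt(144 - 100), abs=1e-12)

    def test_separating_pair_outside_range_has_no_event(self):
        st = two_bead_state((10, 0, 0), (1, 0, 0))
        assert predict_pair_event(st, (0, 1), StepPotential.hard_core(4.0)) is None

    def test_inconsistent_shell_bookkeeping_detected(self):
        st = two_bead_state((10, 0, 0), (-1, 0, 0))
        st.shells = np.array([0])  # geometric shell is 1
        with pytest.raises(RuntimeError, match="inconsistent"):
            predict_pair_event(st, (0, 1), StepPotential.hard_core(4.0))


class TestResolve:
    def test_equal_mass_head_on_bounce_exchanges_velocities(self):
        st = two_bead_state((4.0, 0, 0), (-1, 0, 0))
        ev = engine.Event(time=0.0, kind="core_bounce", i=0, j=1, direction=-1)
        resolve_collision(st, ev, StepPotential.hard_core(4.0))
        np.testing.assert_allclose(st.velocities[0], [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(st.velocities[1], [-1, 0, 0], atol=1e-12)

    def test_well_capture_boosts_radial_speed(self):
        # μ=0.5, inbound vr=1 entering ΔU=−0.5 well: |vr'| = √3
        pot = StepPotential.native_well(4.0, 8.0, 0.5)
        st = two_bead_state((8.0, 0, 0), (-1, 0, 0))
        ev = engine.Event(time=0.0, kind="shell_crossing", i=0, j=1, direction=-1)
        d_pe = resolve_collision(st, ev, pot)
        vr = st.velocities[0, 0] - st.velocities[1, 0]
        assert vr == pytest.approx(-math.sqrt(3), abs=1e-12)
        assert d_pe == pytest.approx(-0.5)

    def test_insufficient_energy_reflects_at_well_edge(self):
        # ½μvr² = 0.25 against a 0.5 step: reflection
        pot = StepPotential.native_well(1.0, 8.0, 0.5)
        st = two_bead_state((8.0, 0, 0), (1, 0, 0), v_j=(0, 0, 0))
        st.shells = None
        # place the pair just inside the well, moving outward
        st.positions[0, 0] = 8.0
        ev = engine.Event(time=0.0, kind="shell_crossing", i=0, j=1, direction=1)
        d_pe = resolve_collision(st, ev, pot)
        vr = st.velocities[0, 0] - st.velocities[1, 0]
        assert vr == pytest.approx(-1.0)
        assert d_pe == 0.0

    def test_momentum_conserved_in_collisions(self):
        rng = np.random.default_rng(0)
        pot = StepPotential.native_well(2.0, 6.0, 1.3)
        for _ in range(20):
            st = two_bead_state(
                (6.0, 0, 0), rng.normal(size=3), v_j=rng.normal(size=3), mass=2.0
            )
            p0 = st.masses[:, None] * st.velocities
            direction = -1 if (st.velocities[0] - st.velocities[1])[0] < 0 else 1
            ev = engine.Event(0.0, "shell_crossing", 0, 1, direction)
            resolve_collision(st, ev, pot)
            p1 = st.masses[:, None] * st.velocities
            np.testing.assert_allclose(p0.sum(axis=0), p1.sum(axis=0), atol=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(
        seed=hyp_st.integers(0, 10_000),
        m1=hyp_st.floats(0.5, 200.0),
        m2=hyp_st.floats(0.5, 200.0),
        depth=hyp_st.floats(0.0, 5.0),
    )
    def test_collision_conserves_energy_and_angular_momentum(
        self, seed, m1, m2, depth
    ):
        """E, p and L are exactly conserved across any single pair event."""
        rng = np.random.default_rng(seed)
        pot = StepPotential.native_well(2.0, 6.0, depth)
        st = SystemState(
            positions=np.array([[6.0, 0, 0], [0.0, 0, 0]]) + rng.normal(size=(2, 3)) * 0,
            velocities=rng.normal(size=(2, 3)),
            masses=np.array([m1, m2]),
        )
        m = st.masses[:, None]
        e0 = st.kinetic_energy + pot.energy_at(6.0 + 1e-9)
        p0 = (m * st.velocities).sum(axis=0)
        l0 = (m * np.cross(st.positions, st.velocities)).sum(axis=0)
        vr = (st.velocities[0] - st.velocities[1])[0]
        direction = -1 if vr < 0 else 1
        ev = engine.Event(0.0, "shell_crossing", 0, 1, direction)
        d_pe = resolve_collision(st, ev, pot)
        e1 = st.kinetic_energy + pot.energy_at(6.0 + 1e-9) + d_pe
        p1 = (m * st.velocities).sum(axis=0)
        l1 = (m * np.cross(st.positions, st.velocities)).sum(axis=0)
        assert e1 == pytest.approx(e0, abs=1e-9)
        np.testing.assert_allclose(p1, p0, atol=1e-9)
        np.testing.assert_allclose(l1, l0, atol=1e-9)


class TestAndersen:
    def test_zero_temperature_gives_zero_velocity(self):
        st = two_bead_state((10, 0, 0), (1, 2, 3))
        andersen_kick(st, 0, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(st.velocities[0], [0, 0, 0])

    def test_kick_variance_matches_temperature(self):
        st = two_bead_state((10, 0, 0), (0, 0, 0))
        rng = np.random.default_rng(1)
        n = 100_000
        draws = np.empty((n, 3))
        for k in range(n):
            andersen_kick(st, 0, 0.6, rng)
            draws[k] = st.velocities[0]
        var = draws.var()
        se = 0.6 * math.sqrt(2 / (3 * n))
        assert abs(var - 0.6) < 3 * se


def ideal_chain(n=8, seed=0):
    """Bonds-plus-hard-core chain (no native wells): zig-zag geometry."""
    top = ChainTopology(n_beads=n, segments=(("tail", 1, n),), bead_mass=10.0)
    model, state = build_mini_bundle(top, seed=seed)
    assert model.pairs_of_class("native") == []
    return model, state


class TestRun:
    def test_static_isolated_beads_stay_put(self):
        st = two_bead_state((100, 0, 0), (0, 0, 0))
        model = InteractionModel(2, StepPotential.hard_core(4.0))
        with pytest.warns(RuntimeWarning, match="no events"):
            traj = engine.run(st, model, 0.5, 50.0, thermostat_rate=0.0, seed=0)
        np.testing.assert_array_equal(traj.positions[0], traj.positions[-1])

    def test_bonded_dimer_oscillates_at_bounce_period(self):
        rmin, rmax = 3.0, 5.0
        model = InteractionModel(2, StepPotential.hard_core(1.0))
        model.set_pair(0, 1, StepPotential((rmin, rmax), (math.inf, 0.0, math.inf)), "bond")
        st = two_bead_state((4.0, 0, 0), (0.25, 0, 0), v_j=(-0.25, 0, 0))
        st.bind_model(model)
        traj = engine.run(
            st, model, 0.5, 100.0, thermostat_rate=0.0, seed=0, collect_events=100
        )
        walls = [e for e in traj.events if e.kind in ("bond_wall", "core_bounce")]
        # consecutive same-wall hits are one full period apart: 2·gap/|vr|
        period = 2 * (rmax - rmin) / 0.5
        outer_hits = [e.time for e in walls[::2]]
        gaps = np.diff(outer_hits)
        np.testing.assert_allclose(gaps, period, atol=1e-9)

    def test_energy_conserved_without_thermostat(self, mini_bundle):
        model, state = mini_bundle
        st = state.copy()
        st.thermalize(0.5, np.random.default_rng(11))
        e0 = st.total_energy
        traj = engine.run(st, model, 0.5, 10_000.0, thermostat_rate=0.0, seed=1)
        assert traj.n_events > 100_000
        # recompute energies from scratch at the final state
        pe = model.potential_energy(st.positions)
        assert abs(pe + st.kinetic_energy - e0) < 1e-6
        # and the bookkept series never drifts
        drift = np.abs(traj.total_energy - traj.total_energy[0])
        assert drift.max() < 1e-6

    def test_momentum_and_angular_momentum_conserved(self, mini_bundle):
        model, state = mini_bundle
        st = state.copy()
        st.thermalize(0.6, np.random.default_rng(3))
        m = st.masses[:, None]
        p0 = (m * st.velocities).sum(axis=0)
        l0 = (m * np.cross(st.positions, st.velocities)).sum(axis=0)
        engine.run(st, model, 0.6, 500.0, thermostat_rate=0.0, seed=2)
        p1 = (m * st.velocities).sum(axis=0)
        l1 = (m * np.cross(st.positions, st.velocities)).sum(axis=0)
        np.testing.assert_allclose(p1, p0, atol=1e-9)
        np.testing.assert_allclose(l1, l0, atol=1e-7)

    def test_no_interpenetration(self, mini_bundle, mini_topology):
        model, state = mini_bundle
        st = state.copy()
        st.thermalize(0.7, np.random.default_rng(5))
        traj = engine.run(st, model, 0.7, 2000.0, thermostat_rate=0.1, seed=4)
        bonded = set(model.pairs_of_class("bond"))
        core = mini_topology.hard_core_diameter
        n = mini_topology.n_beads
        iu = np.triu_indices(n, k=1)
        for f in traj.positions[::8]:
            d = np.linalg.norm(f[iu[0]] - f[iu[1]], axis=1)
            mask = np.array([(i, j) not in bonded for i, j in zip(*iu)])
            assert d[mask].min() >= core - 1e-9

    def test_thermostat_equipartition_and_velocity_normality(self):
        """Ideal chain at T: per-dof kinetic energy T/2; Maxwellian velocities."""
        model, state = ideal_chain(n=8)
        t_target = 0.6
        st = state.copy()
        st.thermalize(t_target, np.random.default_rng(6))
        samples = []
        engine.run(st, model, t_target, 200.0, thermostat_rate=0.2, seed=10)  # settle
        for k in range(500):
            engine.run(st, model, t_target, 20.0, thermostat_rate=0.2, seed=100 + k)
            samples.append(st.velocities.copy())
        v = np.array(samples)  # (500, 8, 3), decorrelated snapshots
        ke_dof = 0.5 * st.masses[None, :, None] * v**2
        block_means = ke_dof.reshape(20, -1).mean(axis=1)
        se = block_means.std(ddof=1) / math.sqrt(len(block_means))
        assert abs(block_means.mean() - t_target / 2) < 3 * se
        scaled = (v * np.sqrt(st.masses)[None, :, None]).ravel()
        assert len(scaled) >= 10_000
        _, p = stats.normaltest(scaled)
        assert p > 0.01

    def test_event_sequence_matches_naive_reference(self):
        """3-bead queued engine vs an O(n²)-per-event reference loop."""
        pot_core = StepPotential.hard_core(2.0)
        model = InteractionModel(3, pot_core)
        model.set_pair(0, 1, StepPotential((2.0, 3.4), (math.inf, 0.0, math.inf)), "bond")
        model.set_pair(0, 2, StepPotential.native_well(2.0, 5.0, 0.8), "native")
        pos = np.array([[0.0, 0, 0], [3.0, 0.4, 0], [5.5, -1.5, 0.3]])
        vel = np.array([[0.1, 0.02, 0.0], [-0.2, 0.1, 0.05], [-0.3, 0.2, -0.1]])
        # horizon short enough that round-off chaos cannot reorder events
        horizon = 50.0

        st = SystemState(pos.copy(), vel.copy(), np.array([1.0, 2.0, 1.5]))
        st.bind_model(model)
        traj = engine.run(
            st, model, 0.5, horizon, thermostat_rate=0.0, seed=0, collect_events=10_000
        )
        got = [(e.time, e.i, e.j) for e in traj.events]

        ref_state = SystemState(pos.copy(), vel.copy(), np.array([1.0, 2.0, 1.5]))
        ref_state.bind_model(model)
        expected = []
        pairs = [(0, 1), (0, 2), (1, 2)]
        while True:
            best = None
            for pair in pairs:
                ev = predict_pair_event(ref_state, pair, model.potential(*pair))
                if ev is not None and (best is None or ev.time < best.time):
                    best = ev
            if best is None or best.time > horizon:
                break
            dt = best.time - ref_state.time
            ref_state.positions += ref_state.velocities * dt
            ref_state.time = best.time
            resolve_collision(ref_state, best, model.potential(best.i, best.j))
            expected.append((best.time, best.i, best.j))

        assert len(got) == len(expected) > 10
        for (tg, ig, jg), (te, ie, je) in zip(got, expected):
            assert (ig, jg) == (ie, je)
            assert tg == pytest.approx(te, abs=1e-7)

    def test_scheduling_window_does_not_change_dynamics(self, mini_bundle):
        model, state = mini_bundle
        st1 = state.copy()
        st2 = state.copy()
        for st in (st1, st2):
            st.thermalize(0.5, np.random.default_rng(12))
        engine.run(st1, model, 0.5, 20.0, thermostat_rate=0.0, seed=3, window=1.0)
        engine.run(st2, model, 0.5, 20.0, thermostat_rate=0.0, seed=3, window=1e6)
        np.testing.assert_allclose(st1.positions, st2.positions, atol=1e-10)
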