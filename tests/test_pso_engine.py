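import math

import numpy as np
import pytest

from swarmclust.cluster_model import (
    ClusterGeometry,
    ConfigError,
    Particle,
    ShapeError,
    SwarmConfig,
    init_swarm,
)
from swarmclust.energy_backends import (
    EnergyResult,
    FunctionBackend,
    LennardJonesBackend,
)
from swarmclust.pso_engine import (
    has_converged,
    inertia_at,
    restart_search,
    run_pso,
    run_pso_dimensions,
    update_bests,
    update_position,
    update_velocity,
)
from .conftest import LJ_REFERENCE


def _fixed_eps_rng(value):
    """Generator stand-in returning `value` for every draw."""

    class _R:
        def random(self, size=None):
            if size is None:
                return value
            return np.full(size, value)

    return _R()


class TestInertia:
    def test_bounds(self):
        cfg = SwarmConfig(max_iter=100)
        assert inertia_at(0, cfg) == pytest.approx(0.8)
        assert inertia_at(100, cfg) == pytest.approx(0.4)

    def test_midpoint(self):
        cfg = SwarmConfig(max_iter=100)
        assert inertia_at(50, cfg) == pytest.approx(0.6)

    def test_constant_mode(self):
        cfg = SwarmConfig(w_min=0.6, w_max=0.6, max_iter=100)
        for it in (0, 13, 100):
            assert inertia_at(it, cfg) == 0.6


class TestVelocityUpdate:
    def test_identity_limit(self):
        cfg = SwarmConfig(d1=0.0, d2=0.0, velocity_clamp=math.inf)
        p = Particle(np.zeros(3), np.array([1.0, -2.0, 0.5]), np.zeros(3))
        v = update_velocity(p, np.zeros(3), w=1.0, config=cfg, rng=_fixed_eps_rng(0.3))
        np.testing.assert_allclose(v, [1.0, -2.0, 0.5])

    def test_attraction_vanishes_at_consensus(self):
        cfg = SwarmConfig(velocity_clamp=math.inf)
        x = np.array([1.0, 2.0, 3.0])
        p = Particle(x.copy(), np.array([0.5, 0.5, 0.5]), x.copy())
        v = update_velocity(p, x.copy(), w=0.7, config=cfg, rng=_fixed_eps_rng(0.9))
        np.testing.assert_allclose(v, 0.7 * np.array([0.5, 0.5, 0.5]))

    def test_hand_computed_scalar_case(self):
        # w=0.4, v=1, x=0, pbest=1, gbest=2, d1=d2=2, eps1=eps2=0.5
        # v' = 0.4*1 + 2*0.5*(1-0) + 2*0.5*(2-0) = 3.4
        cfg = SwarmConfig(velocity_clamp=math.inf)
        p = Particle(np.array([0.0]), np.array([1.0]), np.array([1.0]))
        v = update_velocity(p, np.array([2.0]), w=0.4, config=cfg, rng=_fixed_eps_rng(0.5))
        assert v[0] == pytest.approx(3.4)

    def test_clamp(self):
        cfg = SwarmConfig(velocity_clamp=2.0)
        p = Particle(np.array([0.0]), np.array([10.0]), np.array([0.0]))
        v = update_velocity(p, np.array([0.0]), w=1.0, config=cfg, rng=_fixed_eps_rng(0.0))
        assert v[0] == pytest.approx(2.0)

    def test_shape_mismatch(self):
        cfg = SwarmConfig()
        p = Particle(np.zeros(3), np.zeros(3), np.zeros(3))
        with pytest.raises(ShapeError):
            update_velocity(p, np.zeros(6), w=0.5, config=cfg, rng=_fixed_eps_rng(0.5))


class TestPositionUpdate:
    def test_arithmetic(self):
        cfg = SwarmConfig(velocity_clamp=math.inf)
        x = update_position(np.array([1.0]), np.array([3.4]), cfg)
        assert x[0] == pytest.approx(4.4)

    def test_zero_velocity(self):
        cfg = SwarmConfig()
        np.testing.assert_array_equal(
            update_position(np.array([1.0, 2.0]), np.zeros(2), cfg), [1.0, 2.0]
        )

    def test_clamped_advance(self):
        cfg = SwarmConfig(velocity_clamp=2.0)
        x = update_position(np.array([0.0]), np.array([10.0]), cfg)
        assert x[0] == pytest.approx(2.0)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            update_position(np.zeros(3), np.zeros(4), SwarmConfig())


class TestUpdateBests:
    def _swarm(self):
        swarm = init_swarm(SwarmConfig(n_pop=3, seed=0), n_atoms=1)
        return swarm

    def test_improvement_installs_pbest(self):
        swarm = self._swarm()
        res = [EnergyResult("ok", -1.0), EnergyResult("ok", -2.0), EnergyResult("ok", -0.5)]
        update_bests(swarm, res)
        assert [p.pbest_energy for p in swarm.particles] == [-1.0, -2.0, -0.5]
        assert swarm.gbest_energy == -2.0
        np.testing.assert_array_equal(swarm.gbest_position, swarm.particles[1].position)

    def test_tie_keeps_incumbent(self):
        swarm = self._swarm()
        update_bests(swarm, [EnergyResult("ok", -1.0)] * 3)
        incumbent = swarm.particles[0].pbest_position.copy()
        swarm.particles[0].position = swarm.particles[0].position + 1.0
        update_bests(swarm, [EnergyResult("ok", -1.0)] * 3)
        np.testing.assert_array_equal(swarm.particles[0].pbest_position, incumbent)

    def test_gbest_is_min_of_pbest(self):
        swarm = self._swarm()
        rng = np.random.default_rng(5)
        for _ in range(10):
            energies = [EnergyResult("ok", float(e)) for e in rng.normal(size=3)]
            update_bests(swarm, energies)
            assert swarm.gbest_energy == min(p.pbest_energy for p in swarm.particles)

    def test_wrong_length(self):
        with pytest.raises(ShapeError):
            update_bests(self._swarm(), [EnergyResult("ok", 0.0)])


class TestHasConverged:
    def test_stall_rule_fires(self):
        cfg = SwarmConfig(stall_threshold=30)
        assert has_converged([5.0] + [-1.0] * 31, cfg)

    def test_improvement_resets(self):
        cfg = SwarmConfig(stall_threshold=30, energy_tol=1e-6)
        traj = [-1.0] * 30 + [-1.0 - 10e-6]
        assert not has_converged(traj, cfg)

    def test_short_trajectory(self):
        cfg = SwarmConfig(stall_threshold=30)
        assert not has_converged([-1.0] * 30, cfg)

    def test_tolerance_window(self):
        cfg = SwarmConfig(stall_threshold=3, energy_tol=1e-3)
        assert has_converged([-1.0, -1.0004, -1.0006, -1.0008], cfg)
        assert not has_converged([-1.0, -1.002, -1.002, -1.002], cfg)


class TestRunPso:
    def test_lj3_reaches_global_minimum(self, lj_backend):
        hits = 0
        for seed in range(10):
            r = run_pso(SwarmConfig(seed=seed), lj_backend, n_atoms=3)
            if abs(r.best_energy - LJ_REFERENCE[3]) < 1e-3:
                hits += 1
        assert hits >= 9

    def test_sphere_function(self):
        sphere = FunctionBackend(lambda x: float(np.dot(x, x)), name="sphere")
        r = run_pso_dimensions(SwarmConfig(seed=3, max_iter=500), sphere, 2)
        assert r.best_energy <= 1e-6
        assert r.iterations_used <= 500

    def test_deterministic_repeat(self, lj_backend):
        a = run_pso(SwarmConfig(seed=11, max_iter=60), lj_backend, n_atoms=3)
        b = run_pso(SwarmConfig(seed=11, max_iter=60), lj_backend, n_atoms=3)
        assert a.trajectory == b.trajectory
        np.testing.assert_array_equal(a.best_geometry.coords, b.best_geometry.coords)

    def test_trajectory_non_increasing(self, lj_backend):
        r = run_pso(SwarmConfig(seed=2, max_iter=80), lj_backend, n_atoms=4)
        assert all(b <= a + 1e-15 for a, b in zip(r.trajectory, r.trajectory[1:]))
        assert r.best_energy == r.trajectory[-1]

    def test_requires_exactly_one_start_spec(self, lj_backend):
        with pytest.raises(ConfigError):
            run_pso(SwarmConfig(), lj_backend)
        with pytest.raises(ConfigError):
            run_pso(
                SwarmConfig(),
                lj_backend,
                n_atoms=2,
                start=ClusterGeometry(("C",), [[0, 0, 0]]),
            )

    def test_start_geometry_is_used(self, lj_backend):
        start = ClusterGeometry(("C", "C"), [[0, 0, 0], [2.0 ** (1 / 6), 0, 0]])
        r = run_pso(SwarmConfig(seed=0, max_iter=40), lj_backend, start=start)
        # particle 0 sits at the pair minimum, so gbest starts at -1
        assert r.trajectory[0] == pytest.approx(-1.0)

    def test_inertial_straight_line_motion(self):
        # with d1=d2=0 and w=1, x^t = x^0 + t*v^0 exactly
        flat = FunctionBackend(lambda x: 0.0, name="flat")
        cfg = SwarmConfig(
            d1=0.0, d2=0.0, w_min=1.0, w_max=1.0, max_iter=5,
            stall_threshold=50, velocity_clamp=math.inf, seed=4,
        )
        swarm = init_swarm(cfg, n_atoms=2)
        x0 = [p.position.copy() for p in swarm.particles]
        v0 = [p.velocity.copy() for p in swarm.particles]
        from swarmclust.pso_engine import _run_swarm

        _run_swarm(swarm, cfg, flat, None, 0, ("C", "C"))
        for p, x, v in zip(swarm.particles, x0, v0):
            np.testing.assert_allclose(p.position, x + cfg.max_iter * v, atol=1e-12)

    def test_all_penalty_first_iteration_warns(self):
        fail = FunctionBackend(lambda x: (_ for _ in ()).throw(RuntimeError("down")))
        r = run_pso(SwarmConfig(seed=0, max_iter=35), fail, n_atoms=2)
        assert r.warnings
        assert "penalt" in r.warnings[0]


class TestRestartSearch:
    def test_single_restart_equals_run_pso(self, lj_backend):
        cfg = SwarmConfig(seed=5, max_iter=50, n_restarts=1)
        a = restart_search(cfg, lj_backend, n_atoms=3)
        b = run_pso(cfg, lj_backend, n_atoms=3)
        assert a.best_energy == b.best_energy
        assert a.trajectory == b.trajectory

    def test_self_consistency_stops_early_on_unimodal(self):
        # convex bowl in 6-D: every restart lands at the same minimum
        bowl = FunctionBackend(lambda x: float(np.dot(x, x)), name="bowl")
        cfg = SwarmConfig(seed=1, max_iter=150, n_restarts=5, energy_tol=1e-3)
        r = restart_search(cfg, bowl, n_atoms=2)
        assert r.restarts_used == 2
        assert r.best_energy < 1e-3

    def test_trajectory_monotone_across_restarts(self, lj_backend):
        cfg = SwarmConfig(seed=3, max_iter=60, n_restarts=3, energy_tol=1e-9)
        r = restart_search(cfg, lj_backend, n_atoms=4)
        assert all(b <= a + 1e-15 for a, b in zip(r.trajectory, r.trajectory[1:]))
        assert r.best_energy == r.trajectory[-1]

    def test_deterministic(self, lj_backend):
        cfg = SwarmConfig(seed=9, max_iter=40, n_restarts=2)
        a = restart_search(cfg, lj_backend, n_atoms=3)
        b = restart_search(cfg, lj_backend, n_atoms=3)
        assert a.trajectory == b.trajectory


class TestMonotonicityProperty:
    def test_random_configurations(self, lj_backend):
        # gbest trajectory is non-increasing across many random setups
        rng = np.random.default_rng(0)
        for _ in range(100):
            cfg = SwarmConfig(
                seed=int(rng.integers(0, 2**31)),
                n_pop=int(rng.integers(2, 8)),
                max_iter=int(rng.integers(5, 25)),
                velocity_clamp=float(rng.uniform(0.1, 3.0)),
                eps_mode=str(rng.choice(["scalar", "component"])),
            )
            n_atoms = int(rng.integers(2, 5))
            r = run_pso(cfg, lj_backend, n_atoms=n_atoms)
            assert all(
                b <= a + 1e-15 for a, b in zip(r.trajectory, r.trajectory[1:])
            )
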