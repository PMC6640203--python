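"""Swarm search: velocity/position updates, best-tracking, stall
convergence, and the restart-to-self-consistency outer loop.

Per particle and component j the velocity update is

    v'_j = w*v_j + d1*eps1_j*(pbest_j - x_j) + d2*eps2_j*(gbest_j - x_j)

with eps1, eps2 drawn fresh from the particle's own random substream
(one scalar pair per update by default; optionally per component),
followed by x' = x + v'.  The inertia weight w descends
linearly from w_max to w_min across max_iter iterations.  A run terminates
when the global-best energy has been flat (within energy_tol) for
stall_threshold successive iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cluster_model import (
    ClusterGeometry,
    ConfigError,
    Particle,
    ShapeError,
    Swarm,
    SwarmConfig,
    flatten_geometry,
    init_swarm,
    particle_rng,
    unflatten,
)
from .energy_backends import EnergyBackend, EnergyResult, PENALTY_ENERGY
from .parallel_executor import ExecutorConfig, evaluate_swarm

__all__ = [
    "RunResult",
    "inertia_at",
    "update_velocity",
    "update_position",
    "update_bests",
    "has_converged",
    "run_pso",
    "restart_search",
]


@dataclass
class RunResult:
    """Outcome of one search run (any method)."""

    best_geometry: ClusterGeometry
    best_energy: float
    trajectory: list[float]
    iterations_used: int
    converged: bool
    restarts_used: int = 0
    evaluations: int = 0
    method: str = "pso"
    warnings: list[str] = field(default_factory=list)
    # raw best vector; equals the flattened best_geometry for 3n-dimensional
    # problems and is the only faithful record for other dimensionalities
    best_position: np.ndarray | None = None
    # method-specific diagnostics (e.g. SA acceptance counts)
    extras: dict = field(default_factory=dict)
    # one row per iteration: (restart, iteration, gbest, evaluations, stall)
    table: list[tuple[int, int, float, int, int]] = field(default_factory=list)


def inertia_at(iteration: int, config: SwarmConfig) -> float:
    """Linear descent from w_max (iteration 0) to w_min (max_iter)."""
    if config.w_min == config.w_max:
        return config.w_max
    frac = min(max(iteration, 0), config.max_iter) / config.max_iter
    return config.w_max - (config.w_max - config.w_min) * frac


def update_velocity(
    particle: Particle,
    gbest: np.ndarray,
    w: float,
    config: SwarmConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One velocity update; stochastic coefficients drawn from the
    particle's own substream (scalar or per-component per config); the
    result is clamped to ±velocity_clamp."""
    gbest = np.asarray(gbest, dtype=float)
    if gbest.shape != particle.position.shape:
        raise ShapeError(
            f"gbest shape {gbest.shape} != particle shape {particle.position.shape}"
        )
    gen = rng if rng is not None else particle.rng
    if gen is None:
        raise ConfigError("particle has no random substream and no rng was supplied")
    if config.eps_mode == "scalar":
        eps1 = gen.random()
        eps2 = gen.random()
    else:
        dim = particle.position.size
        eps1 = gen.random(dim)
        eps2 = gen.random(dim)
    v = (
        w * particle.velocity
        + config.d1 * eps1 * (particle.pbest_position - particle.position)
        + config.d2 * eps2 * (gbest - particle.position)
    )
    clamp = config.resolved_velocity_clamp
    if math.isfinite(clamp):
        np.clip(v, -clamp, clamp, out=v)
    return v


def update_position(
    position: np.ndarray, velocity: np.ndarray, config: SwarmConfig
) -> np.ndarray:
    """x' = x + v' (velocity clamped; no positional walls after init)."""
    position = np.asarray(position, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if position.shape != velocity.shape:
        raise ShapeError(f"position {position.shape} vs velocity {velocity.shape}")
    clamp = config.resolved_velocity_clamp
    if math.isfinite(clamp):
        velocity = np.clip(velocity, -clamp, clamp)
    return position + velocity


def update_bests(swarm: Swarm, energies: Sequence[EnergyResult]) -> Swarm:
    """Install strictly better personal bests, then recompute the global best.

    Ties keep the incumbent (both for pbest and gbest).  Mutates and
    returns the swarm.
    """
    if len(energies) != swarm.n_pop:
        raise ShapeError(f"{len(energies)} energies for {swarm.n_pop} particles")
    for particle, result in zip(swarm.particles, energies):
        if result.energy < particle.pbest_energy:
            particle.pbest_energy = float(result.energy)
            particle.pbest_position = particle.position.copy()
    for particle in swarm.particles:
        if particle.pbest_energy < swarm.gbest_energy:
            swarm.gbest_energy = particle.pbest_energy
            swarm.gbest_position = particle.pbest_position.copy()
    return swarm


def has_converged(trajectory: Sequence[float], config: SwarmConfig) -> bool:
    """Stall rule: the last stall_threshold+1 global-best energies agree
    within energy_tol (i.e. stall_threshold successive iterations without
    change)."""
    window = config.stall_threshold + 1
    if len(trajectory) < window:
        return False
    tail = np.asarray(trajectory[-window:], dtype=float)
    return bool(tail.max() - tail.min() <= config.energy_tol)


def _stall_count(trajectory: Sequence[float], tol: float) -> int:
    """Number of most-recent successive iterations without improvement."""
    count = 0
    for i in range(len(trajectory) - 1, 0, -1):
        if abs(trajectory[i] - trajectory[i - 1]) <= tol:
            count += 1
        else:
            break
    return count


def _run_swarm(
    swarm: Swarm,
    config: SwarmConfig,
    backend: EnergyBackend,
    exec_config: ExecutorConfig | None,
    restart_index: int,
    elements: tuple[str, ...],
) -> RunResult:
    trajectory: list[float] = []
    table: list[tuple[int, int, float, int, int]] = []
    warnings: list[str] = []
    evaluations = 0
    converged = False

    for it in range(config.max_iter):
        swarm.iteration = it
        tag_prefix = f"run_{restart_index}_{it}"
        energies = evaluate_swarm(swarm, backend, exec_config, tag_prefix=tag_prefix)
        evaluations += len(energies)
        if it == 0 and all(e.energy >= PENALTY_ENERGY for e in energies):
            warnings.append(
                "all first-iteration evaluations were penalties "
                "(overlaps or engine failures); continuing"
            )
        update_bests(swarm, energies)
        trajectory.append(swarm.gbest_energy)
        table.append(
            (
                restart_index,
                it,
                swarm.gbest_energy,
                evaluations,
                _stall_count(trajectory, config.energy_tol),
            )
        )
        if has_converged(trajectory, config):
            converged = True
            break
        w = inertia_at(it, config)
        for particle in swarm.particles:
            particle.velocity = update_velocity(particle, swarm.gbest_position, w, config)
            particle.position = update_position(particle.position, particle.velocity, config)

    gbest = np.asarray(swarm.gbest_position, dtype=float)
    if gbest.size % 3 == 0 and gbest.size == 3 * len(elements):
        best_geom = unflatten(gbest, elements)
    else:  # non-geometric objective: placeholder geometry, vector is authoritative
        best_geom = ClusterGeometry(("X",), np.zeros((1, 3)))
    return RunResult(
        best_geometry=best_geom,
        best_position=gbest,
        best_energy=swarm.gbest_energy,
        trajectory=trajectory,
        iterations_used=len(trajectory),
        converged=converged,
        restarts_used=0,
        evaluations=evaluations,
        method="pso",
        warnings=warnings,
        table=table,
    )


def _resolve_elements(n_atoms: int, elements: Sequence[str] | None) -> tuple[str, ...]:
    if elements is None:
        return ("C",) * n_atoms
    if len(elements) != n_atoms:
        raise ShapeError(f"{len(elements)} element symbols for {n_atoms} atoms")
    return tuple(elements)


def run_pso(
    config: SwarmConfig,
    backend: EnergyBackend,
    n_atoms: int | None = None,
    start: ClusterGeometry | None = None,
    elements: Sequence[str] | None = None,
    exec_config: ExecutorConfig | None = None,
    restart_index: int = 0,
) -> RunResult:
    """One full swarm search.

    Provide either ``n_atoms`` (random initialization in the configured
    range) or ``start`` (particle 0 placed exactly at the start geometry,
    the rest initialized randomly).  A fixed ``config.seed`` yields an
    identical RunResult regardless of worker count.
    """
    if (n_atoms is None) == (start is None):
        raise ConfigError("provide exactly one of n_atoms or start")
    if start is not None:
        n_atoms = start.n_atoms
        elements = start.elements
    assert n_atoms is not None
    elems = _resolve_elements(n_atoms, elements)
    swarm = init_swarm(config, n_atoms, restart=restart_index)
    if start is not None:
        v0 = flatten_geometry(start)
        swarm.particles[0].position = v0.copy()
        swarm.particles[0].pbest_position = v0.copy()
    return _run_swarm(swarm, config, backend, exec_config, restart_index, elems)


def run_pso_dimensions(
    config: SwarmConfig,
    backend: EnergyBackend,
    dimensions: int,
    exec_config: ExecutorConfig | None = None,
) -> RunResult:
    """Swarm search over a plain d-dimensional objective (non-geometric
    backends; used for analytic test functions).  The returned
    best_geometry is a placeholder single-atom geometry when d is not a
    multiple of 3."""
    if dimensions < 1:
        raise ConfigError("dimensions must be >= 1")
    # reuse the per-particle substream machinery with a fake atom count
    swarm = init_swarm(config, max(dimensions // 3, 1), restart=0)
    vmax = 0.1 * config.init_width
    for i, particle in enumerate(swarm.particles):
        gen = particle_rng(config.seed, 0, i)
        particle.position = gen.uniform(config.init_low, config.init_high, size=dimensions)
        particle.velocity = gen.uniform(-vmax, vmax, size=dimensions)
        particle.pbest_position = particle.position.copy()
        particle.rng = gen
    return _run_swarm(swarm, config, backend, exec_config, 0, ("X",))


def restart_search(
    config: SwarmConfig,
    backend: EnergyBackend,
    n_atoms: int,
    elements: Sequence[str] | None = None,
    exec_config: ExecutorConfig | None = None,
) -> RunResult:
    """Outer self-consistency loop over restarted swarm searches.

    After each inner run a new swarm is seeded from the incumbent best:
    half the particles perturb it with zero-mean Gaussian noise
    (sigma = restart_noise_sigma), the other half are fresh uniform draws.
    The loop stops early once two consecutive restarts agree on the best
    energy within energy_tol.
    """
    elems = _resolve_elements(n_atoms, elements)
    dim = 3 * n_atoms
    vmax = 0.1 * config.init_width

    overall_best_energy = math.inf
    overall_best_vec: np.ndarray | None = None
    trajectory: list[float] = []
    table: list[tuple[int, int, float, int, int]] = []
    warnings: list[str] = []
    evaluations = 0
    iterations = 0
    converged = False
    prev_best = None
    restarts_used = 0

    for r in range(config.n_restarts):
        restarts_used = r + 1
        if r == 0 or overall_best_vec is None:
            swarm = init_swarm(config, n_atoms, restart=r)
        else:
            particles = []
            for i in range(config.n_pop):
                gen = particle_rng(config.seed, r, i)
                if i < config.n_pop // 2:
                    pos = overall_best_vec + gen.normal(
                        0.0, config.restart_noise_sigma, size=dim
                    )
                else:
                    pos = gen.uniform(config.init_low, config.init_high, size=dim)
                vel = gen.uniform(-vmax, vmax, size=dim)
                particles.append(
                    Particle(
                        position=pos,
                        velocity=vel,
                        pbest_position=pos.copy(),
                        rng=gen,
                    )
                )
            swarm = Swarm(particles=particles)
        inner = _run_swarm(swarm, config, backend, exec_config, r, elems)
        evaluations += inner.evaluations
        iterations += inner.iterations_used
        warnings.extend(inner.warnings)
        table.extend(inner.table)
        if inner.best_energy < overall_best_energy:
            overall_best_energy = inner.best_energy
            overall_best_vec = flatten_geometry(inner.best_geometry)
        # outer trajectory is the running best, so it stays non-increasing
        for e in inner.trajectory:
            trajectory.append(e if not trajectory else min(e, trajectory[-1]))
        converged = inner.converged
        if prev_best is not None and abs(inner.best_energy - prev_best) <= config.energy_tol:
            break  # self-consistency between consecutive restarts
        prev_best = inner.best_energy

    assert overall_best_vec is not None
    return RunResult(
        best_geometry=unflatten(overall_best_vec, elems),
        best_position=overall_best_vec,
        best_energy=overall_best_energy,
        trajectory=trajectory,
        iterations_used=iterations,
        converged=converged,
        restarts_used=restarts_used,
        evaluations=evaluations,
        method="pso+restart",
        warnings=warnings,
        table=table,
    )
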