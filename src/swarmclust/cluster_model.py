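"""Data model for clusters, particles, and swarms.

A cluster of ``n`` atoms is searched in a flat 3n-dimensional space: atom
``i`` occupies slots ``(3i, 3i+1, 3i+2)`` of the position vector.  This
module owns the geometry <-> flat-vector encoding, the swarm containers,
and seeded random initialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "ShapeError",
    "ConfigError",
    "ClusterGeometry",
    "Particle",
    "Swarm",
    "SwarmConfig",
    "flatten_geometry",
    "unflatten",
    "init_swarm",
    "min_pair_distance",
    "particle_rng",
]

PBEST_UNSET = math.inf  # sentinel until a particle's first evaluation


class ShapeError(ValueError):
    """Vector/geometry dimensions do not line up."""


class ConfigError(ValueError):
    """A configuration value violates its invariants."""


@dataclass(frozen=True)
class ClusterGeometry:
    """Element symbols plus per-atom Cartesian coordinates in Å.

    Coordinates are stored as an ``(n, 3)`` float array; the instance owns
    a private copy so callers cannot mutate it afterwards.
    """

    elements: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        elements = tuple(str(e) for e in self.elements)
        coords = np.array(self.coords, dtype=float, copy=True)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ShapeError(f"coords must be (n, 3), got shape {coords.shape}")
        if len(elements) != coords.shape[0]:
            raise ShapeError(
                f"{len(elements)} element symbols but {coords.shape[0]} coordinate rows"
            )
        if len(elements) < 1:
            raise ShapeError("a cluster needs at least one atom")
        if not np.all(np.isfinite(coords)):
            raise ShapeError("coordinates must be finite")
        coords.setflags(write=False)
        object.__setattr__(self, "elements", elements)
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def flatten_geometry(geom: ClusterGeometry) -> np.ndarray:
    """Encode a geometry as a flat length-3n vector (atom i -> slots 3i..3i+2)."""
    return np.array(geom.coords, dtype=float).reshape(-1)


def unflatten(vec: Sequence[float], elements: Sequence[str]) -> ClusterGeometry:
    """Inverse of :func:`flatten_geometry`."""
    vec = np.asarray(vec, dtype=float)
    if vec.ndim != 1:
        raise ShapeError(f"position vector must be 1-D, got {vec.ndim}-D")
    if vec.size % 3 != 0:
        raise ShapeError(f"vector length {vec.size} is not divisible by 3")
    if vec.size != 3 * len(elements):
        raise ShapeError(
            f"vector length {vec.size} does not match {len(elements)} atoms"
        )
    return ClusterGeometry(tuple(elements), vec.reshape(-1, 3))


def min_pair_distance(vec: Sequence[float]) -> float:
    """Minimum interatomic distance; ``inf`` for a single atom (no pairs)."""
    vec = np.asarray(vec, dtype=float)
    if vec.size % 3 != 0:
        raise ShapeError(f"vector length {vec.size} is not divisible by 3")
    coords = vec.reshape(-1, 3)
    if coords.shape[0] < 2:
        return math.inf
    return float(pdist(coords).min())


@dataclass
class Particle:
    """One swarm member: current state plus personal-best memory."""

    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_energy: float = PBEST_UNSET
    rng: np.random.Generator | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.pbest_position = np.asarray(self.pbest_position, dtype=float)
        if not (
            self.position.shape == self.velocity.shape == self.pbest_position.shape
        ):
            raise ShapeError("position, velocity and pbest_position must share a shape")


@dataclass
class Swarm:
    """The population, global-best memory, and the iteration counter."""

    particles: list[Particle]
    gbest_position: np.ndarray | None = None
    gbest_energy: float = math.inf
    iteration: int = 0

    @property
    def n_pop(self) -> int:
        return len(self.particles)


@dataclass(frozen=True)
class SwarmConfig:
    """All swarm-search parameters.

    Defaults follow the published parameter table (population 10, inertia
    0.4-0.8, both acceleration coefficients 2, initialization range (-3, 3),
    30-iteration stall rule); the remaining knobs are engine-agnostic search
    controls.

    ``velocity_clamp=None`` (the default) resolves to
    ``0.075 * (init_high - init_low)``; pass ``math.inf`` to disable
    clamping.  ``eps_mode`` selects the granularity of the stochastic
    coefficients in the velocity update: ``"scalar"`` (one eps1/eps2 pair
    per particle per iteration, as the update equations are written) or
    ``"component"`` (fresh pair per vector component; explores better in
    high-dimensional spaces).
    """

    n_pop: int = 10
    w_min: float = 0.4
    w_max: float = 0.8
    d1: float = 2.0
    d2: float = 2.0
    init_low: float = -3.0
    init_high: float = 3.0
    stall_threshold: int = 30
    energy_tol: float = 1e-6
    max_iter: int = 200
    velocity_clamp: float | None = None
    eps_mode: str = "scalar"
    n_restarts: int = 4
    restart_noise_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pop < 2:
            raise ConfigError(f"n_pop must be >= 2, got {self.n_pop}")
        if self.w_min > self.w_max:
            raise ConfigError(f"w_min ({self.w_min}) exceeds w_max ({self.w_max})")
        if not self.init_low < self.init_high:
            raise ConfigError(
                f"init_low ({self.init_low}) must be strictly below init_high "
                f"({self.init_high})"
            )
        if self.stall_threshold < 1:
            raise ConfigError("stall_threshold must be >= 1")
        if self.energy_tol <= 0:
            raise ConfigError("energy_tol must be positive")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")
        if self.velocity_clamp is not None and self.velocity_clamp <= 0:
            raise ConfigError("velocity_clamp must be positive (or None for default)")
        if self.eps_mode not in ("scalar", "component"):
            raise ConfigError(f"eps_mode must be 'scalar' or 'component', got {self.eps_mode!r}")

    @property
    def init_width(self) -> float:
        return self.init_high - self.init_low

    @property
    def resolved_velocity_clamp(self) -> float:
        if self.velocity_clamp is None:
            return 0.075 * self.init_width
        return self.velocity_clamp


def particle_rng(seed: int, restart: int, particle_id: int) -> np.random.Generator:
    """Independent per-particle random substream.

    Keyed by (root seed, restart index, particle id) so serial and parallel
    runs consume identical random numbers in identical order, and so restart
    swarms never reuse a stream.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(restart), int(particle_id)))
    return np.random.default_rng(ss)


def init_swarm(
    config: SwarmConfig,
    n_atoms: int,
    rng: int | np.random.SeedSequence | None = None,
    *,
    restart: int = 0,
) -> Swarm:
    """Build a fresh swarm with positions uniform in (init_low, init_high).

    ``rng`` is a root *seed* (int), not a Generator: per-particle substreams
    are keyed by particle id, which a shared stateful generator cannot
    provide.  Defaults to ``config.seed``.  Initial velocity components are
    uniform in ±10% of the initialization width.  Personal bests start at
    the initial position with a +inf energy sentinel, so the first
    evaluation always installs a real pbest.
    """
    if n_atoms < 1:
        raise ConfigError(f"n_atoms must be >= 1, got {n_atoms}")
    if isinstance(rng, np.random.SeedSequence):
        seed = rng.entropy
    elif rng is None:
        seed = config.seed
    else:
        seed = int(rng)

    dim = 3 * n_atoms
    vmax = 0.1 * config.init_width
    particles = []
    for i in range(config.n_pop):
        gen = particle_rng(seed, restart, i)
        pos = gen.uniform(config.init_low, config.init_high, size=dim)
        vel = gen.uniform(-vmax, vmax, size=dim)
        particles.append(
            Particle(
                position=pos,
                velocity=vel,
                pbest_position=pos.copy(),
                pbest_energy=PBEST_UNSET,
                rng=gen,
            )
        )
    return Swarm(particles=particles)
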