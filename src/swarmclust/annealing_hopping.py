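"""Comparator searchers over the same backend contract: simulated
annealing (Metropolis walk with a slow cooling schedule) and basin
hopping (perturb -> local minimize -> Metropolis accept on basin
energies), plus the gradient-based local minimizer basin hopping needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .cluster_model import ConfigError, unflatten
from .energy_backends import EnergyBackend, evaluate
from .pso_engine import RunResult

__all__ = [
    "SAConfig",
    "BHConfig",
    "CapabilityError",
    "sa_accept",
    "run_sa",
    "local_minimize",
    "run_bh",
]


class CapabilityError(TypeError):
    """The chosen backend cannot support this operation."""


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing parameters.

    ``schedule`` is "geometric" (T <- alpha*T every steps_per_T steps) or
    "linear" (T descends linearly from T0 to ~0 across max_steps).
    """

    T0: float = 1.0
    alpha: float = 0.95
    steps_per_T: int = 100
    step_size: float = 0.1
    max_steps: int = 20000
    seed: int = 0
    schedule: str = "geometric"
    step_decay: float = 1.0  # optional per-stage shrink of the move size

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ConfigError("T0 must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.steps_per_T < 1 or self.max_steps < 1:
            raise ConfigError("steps_per_T and max_steps must be >= 1")
        if self.step_size <= 0:
            raise ConfigError("step_size must be positive")
        if self.schedule not in ("geometric", "linear"):
            raise ConfigError(f"unknown schedule {self.schedule!r}")
        if not 0 < self.step_decay <= 1:
            raise ConfigError("step_decay must lie in (0, 1]")


@dataclass(frozen=True)
class BHConfig:
    """Basin-hopping parameters."""

    perturb_delta: float = 0.4
    accept_T: float = 1.0
    max_hops: int = 100
    minimizer_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perturb_delta < 0:
            raise ConfigError("perturb_delta must be >= 0")
        if self.accept_T < 0:
            raise ConfigError("accept_T must be >= 0")
        if self.max_hops < 1:
            raise ConfigError("max_hops must be >= 1")
        if self.minimizer_tol <= 0:
            raise ConfigError("minimizer_tol must be positive")


def sa_accept(delta_E: float, T: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: downhill always; uphill with probability exp(-dE/T)."""
    if T <= 0:
        raise ConfigError("temperature must be positive")
    if delta_E <= 0:
        return True
    if not math.isfinite(delta_E):
        return False
    ratio = delta_E / T
    if ratio > 700:  # exp underflow guard
        return False
    return bool(rng.random() < math.exp(-ratio))


def _temperature(config: SAConfig, step: int) -> float:
    if config.schedule == "linear":
        frac = step / config.max_steps
        return max(config.T0 * (1.0 - frac), config.T0 * 1e-12)
    stage = step // config.steps_per_T
    return config.T0 * config.alpha**stage


def run_sa(
    config: SAConfig,
    backend: EnergyBackend,
    start: Sequence[float],
    elements: Sequence[str] | None = None,
) -> RunResult:
    """Metropolis walk with per-coordinate uniform moves and slow cooling.

    The best-ever configuration is tracked and returned; penalty energies
    (engine failures / overlaps) are never accepted over finite energies
    because their delta_E is hugely positive.
    """
    rng = np.random.default_rng(config.seed)
    current = np.asarray(start, dtype=float).copy()
    dim = current.size
    cur_res = evaluate(backend, current)
    cur_e = cur_res.energy
    best = current.copy()
    best_e = cur_e
    trajectory = [best_e]
    evaluations = 1
    accepted_uphill = 0

    for step in range(config.max_steps):
        T = _temperature(config, step)
        width = config.step_size * config.step_decay ** (step // config.steps_per_T)
        proposal = current + rng.uniform(-width, width, size=dim)
        res = evaluate(backend, proposal)
        evaluations += 1
        delta = res.energy - cur_e
        if sa_accept(delta, T, rng):
            if delta > 0:
                accepted_uphill += 1
            current = proposal
            cur_e = res.energy
            if cur_e < best_e:
                best_e = cur_e
                best = current.copy()
        trajectory.append(best_e)

    n_atoms = dim // 3 if dim % 3 == 0 else 1
    elems = tuple(elements) if elements is not None else ("C",) * n_atoms
    geom = unflatten(best if dim % 3 == 0 else np.zeros(3 * n_atoms), elems)
    tail = trajectory[-max(len(trajectory) // 10, 2):]
    return RunResult(
        best_geometry=geom,
        best_position=best,
        best_energy=best_e,
        trajectory=trajectory,
        iterations_used=config.max_steps,
        converged=(max(tail) - min(tail)) <= 1e-12,
        evaluations=evaluations,
        method="sa",
        warnings=[],
        table=[(0, i, e, i + 1, 0) for i, e in enumerate(trajectory)],
        extras={"accepted_uphill": accepted_uphill},
    )


def local_minimize(
    start: Sequence[float],
    backend: EnergyBackend,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> tuple[np.ndarray, float]:
    """Quasi-Newton descent to a stationary point (||grad||_2 <= tol).

    Requires an analytic-gradient backend; external single-point engines
    cannot be minimized locally here — use the swarm or SA searchers for
    those.
    """
    if not backend.has_gradient:
        raise CapabilityError(
            f"backend {backend.name!r} supplies no gradient; local minimization "
            "is unavailable — use the PSO or SA searchers instead"
        )
    x0 = np.asarray(start, dtype=float).copy()
    e0 = evaluate(backend, x0).energy

    def fun(x: np.ndarray) -> float:
        return evaluate(backend, x).energy

    def jac(x: np.ndarray) -> np.ndarray:
        try:
            return backend.gradient(x)
        except Exception:
            return np.zeros_like(x)

    x, e = x0, e0
    gtol = tol
    for _ in range(3):  # polish until the 2-norm criterion holds
        res = _scipy_minimize(fun, x, jac=jac, method="BFGS",
                              options={"gtol": gtol, "maxiter": max_iter})
        if res.fun <= e:
            x, e = np.asarray(res.x, dtype=float), float(res.fun)
        if np.linalg.norm(backend.gradient(x)) <= tol:
            break
        gtol *= 0.01
    if e > e0:  # never report worse than the start
        return x0, e0
    return x, e


def run_bh(
    config: BHConfig,
    backend: EnergyBackend,
    start: Sequence[float],
    elements: Sequence[str] | None = None,
) -> RunResult:
    """Basin hopping: perturb, minimize into the local basin, Metropolis-
    accept on the minimized energies, repeat; best basin wins."""
    if not backend.has_gradient:
        raise CapabilityError(
            f"backend {backend.name!r} supplies no gradient; basin hopping "
            "needs local minimization — use the PSO or SA searchers instead"
        )
    rng = np.random.default_rng(config.seed)
    current, cur_e = local_minimize(start, backend, tol=config.minimizer_tol)
    best, best_e = current.copy(), cur_e
    trajectory = [best_e]
    evaluations = 1

    for _hop in range(config.max_hops):
        proposal = current + rng.uniform(
            -config.perturb_delta, config.perturb_delta, size=current.size
        )
        cand, cand_e = local_minimize(proposal, backend, tol=config.minimizer_tol)
        evaluations += 1
        delta = cand_e - cur_e
        if delta <= 0 or (
            config.accept_T > 0 and sa_accept(delta, config.accept_T, rng)
        ):
            current, cur_e = cand, cand_e
            if cur_e < best_e:
                best, best_e = current.copy(), cur_e
        trajectory.append(best_e)

    dim = best.size
    n_atoms = dim // 3
    elems = tuple(elements) if elements is not None else ("C",) * n_atoms
    tail = trajectory[-max(len(trajectory) // 5, 2):]
    return RunResult(
        best_geometry=unflatten(best, elems),
        best_position=best,
        best_energy=best_e,
        trajectory=trajectory,
        iterations_used=config.max_hops,
        converged=(max(tail) - min(tail)) <= 1e-12,
        evaluations=evaluations,
        method="bh",
        warnings=[],
        table=[(0, i, e, i + 1, 0) for i, e in enumerate(trajectory)],
    )
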