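"""Barrier-synchronized per-particle energy evaluation.

One job per particle, at most ``n_workers`` concurrent; the call returns
only after every job has finished, so iteration-end processing (best
updates, velocity refresh) never overlaps evaluation.  Workers are pure
functions of their inputs — all randomness is consumed in the coordinator
before dispatch — so results are identical for any worker count.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path

from .cluster_model import ConfigError, Swarm
from .energy_backends import PENALTY_ENERGY, EnergyBackend, EnergyResult, evaluate

__all__ = ["ExecutorConfig", "evaluate_swarm"]


@dataclass(frozen=True)
class ExecutorConfig:
    """Worker-count and per-job resource hyper-parameters."""

    n_workers: int = 1
    per_job_timeout: float | None = None
    scratch_root: str | Path | None = None

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ConfigError("n_workers must be >= 1")
        if self.per_job_timeout is not None and self.per_job_timeout <= 0:
            raise ConfigError("per_job_timeout must be positive")


def evaluate_swarm(
    swarm: Swarm,
    backend: EnergyBackend,
    exec_config: ExecutorConfig | None = None,
    tag_prefix: str = "run_0_0",
) -> list[EnergyResult]:
    """Evaluate every particle; results[i] corresponds to particles[i].

    A job exceeding ``per_job_timeout`` yields an ``engine_failed`` penalty
    result for that particle only; the barrier still completes and all
    other results are returned normally.
    """
    cfg = exec_config or ExecutorConfig()
    tags = [f"{tag_prefix}_{i}" for i in range(swarm.n_pop)]

    if cfg.n_workers == 1 and cfg.per_job_timeout is None:
        return [
            evaluate(backend, p.position, tag=tag)
            for p, tag in zip(swarm.particles, tags)
        ]

    results: list[EnergyResult | None] = [None] * swarm.n_pop
    pool = ThreadPoolExecutor(max_workers=cfg.n_workers)
    timed_out = False
    try:
        futures = [
            pool.submit(evaluate, backend, p.position, tag)
            for p, tag in zip(swarm.particles, tags)
        ]
        for i, future in enumerate(futures):
            try:
                results[i] = future.result(timeout=cfg.per_job_timeout)
            except TimeoutError:
                timed_out = True
                future.cancel()
                results[i] = EnergyResult(
                    "engine_failed",
                    PENALTY_ENERGY,
                    backend.unit,
                    f"job exceeded per_job_timeout={cfg.per_job_timeout}s",
                )
    finally:
        # a hung worker thread cannot be joined; abandon it rather than
        # block the barrier for the healthy jobs
        pool.shutdown(wait=not timed_out, cancel_futures=True)
    return results  # type: ignore[return-value]
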