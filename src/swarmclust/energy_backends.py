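"""Energy-evaluation backends behind a single contract.

Every backend maps a flat position vector to an :class:`EnergyResult`.
Analytic pair potentials (Lennard-Jones, Morse) serve desk-scale runs and
supply gradients; the external adapter reproduces the system-call coupling
to a quantum-chemistry engine (render input deck -> invoke -> parse log);
the mock engine exercises that full pipeline in-process.

Failures never raise out of :func:`evaluate`: overlapping atoms and engine
failures are encoded in the result status and scored with a large finite
penalty so the swarm update stays well-defined.
"""

from __future__ import annotations

import math
import re
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .cluster_model import ClusterGeometry, ConfigError, min_pair_distance, unflatten

__all__ = [
    "PENALTY_ENERGY",
    "EnergyResult",
    "OverlapError",
    "TemplateError",
    "LennardJonesParams",
    "MorseParams",
    "EngineTemplate",
    "lj_energy",
    "lj_gradient",
    "morse_energy",
    "morse_gradient",
    "render_deck",
    "parse_energy",
    "evaluate",
    "make_backend",
    "LennardJonesBackend",
    "MorseBackend",
    "FunctionBackend",
    "MockEngineBackend",
    "ExternalEngineBackend",
]

# Finite penalty for failed/rejected evaluations: large enough never to win
# a personal best against any physical energy, small enough to keep the
# velocity update arithmetic finite.
PENALTY_ENERGY = 1.0e6


class OverlapError(ValueError):
    """Two atoms coincide; the potential is undefined there."""


class TemplateError(ValueError):
    """An engine input-deck template is malformed."""


@dataclass(frozen=True)
class EnergyResult:
    """Outcome of a single energy evaluation."""

    status: str  # "ok" | "engine_failed" | "overlap_rejected"
    energy: float
    unit: str = "model"
    diagnostics: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("ok", "engine_failed", "overlap_rejected"):
            raise ConfigError(f"unknown status {self.status!r}")
        if self.status == "ok" and not math.isfinite(self.energy):
            raise ConfigError("status 'ok' requires a finite energy")


# ---------------------------------------------------------------------------
# analytic pair potentials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LennardJonesParams:
    epsilon: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ConfigError("Lennard-Jones epsilon and sigma must be positive")


@dataclass(frozen=True)
class MorseParams:
    d_e: float = 1.0
    a: float = 1.0
    r_e: float = 1.0

    def __post_init__(self) -> None:
        if self.d_e <= 0 or self.a <= 0 or self.r_e <= 0:
            raise ConfigError("Morse D_e, a and r_e must be positive")


def _pair_distances(vec: Sequence[float]) -> np.ndarray:
    coords = np.asarray(vec, dtype=float).reshape(-1, 3)
    return pdist(coords)


def lj_energy(vec: Sequence[float], params: LennardJonesParams = LennardJonesParams()) -> float:
    """Sum over atom pairs of 4*eps*((sigma/r)^12 - (sigma/r)^6)."""
    r = _pair_distances(vec)
    if r.size and r.min() == 0.0:
        raise OverlapError("coincident atoms: Lennard-Jones energy undefined")
    sr6 = (params.sigma / r) ** 6
    return float(np.sum(4.0 * params.epsilon * (sr6 * sr6 - sr6)))


def lj_gradient(
    vec: Sequence[float], params: LennardJonesParams = LennardJonesParams()
) -> np.ndarray:
    """Analytic gradient of :func:`lj_energy` (same length as ``vec``)."""
    coords = np.asarray(vec, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    if n == 1:
        return np.zeros(3)
    r = pdist(coords)
    if r.min() == 0.0:
        raise OverlapError("coincident atoms: Lennard-Jones gradient undefined")
    sr6 = (params.sigma / r) ** 6
    # dphi/dr divided by r, per pair
    coef = 4.0 * params.epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / (r * r)
    cmat = squareform(coef)
    diff = coords[:, None, :] - coords[None, :, :]
    grad = np.einsum("ij,ijk->ik", cmat, diff)
    return grad.reshape(-1)


def morse_energy(vec: Sequence[float], params: MorseParams = MorseParams()) -> float:
    """Sum over pairs of D_e*((1 - exp(-a*(r - r_e)))^2 - 1)."""
    r = _pair_distances(vec)
    ex = np.exp(-params.a * (r - params.r_e))
    return float(np.sum(params.d_e * ((1.0 - ex) ** 2 - 1.0)))


def morse_gradient(vec: Sequence[float], params: MorseParams = MorseParams()) -> np.ndarray:
    coords = np.asarray(vec, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    if n == 1:
        return np.zeros(3)
    r = pdist(coords)
    if r.min() == 0.0:
        raise OverlapError("coincident atoms: pair direction undefined")
    ex = np.exp(-params.a * (r - params.r_e))
    coef = 2.0 * params.d_e * params.a * ex * (1.0 - ex) / r
    cmat = squareform(coef)
    diff = coords[:, None, :] - coords[None, :, :]
    grad = np.einsum("ij,ijk->ik", cmat, diff)
    return grad.reshape(-1)


# ---------------------------------------------------------------------------
# backend classes
# ---------------------------------------------------------------------------


class EnergyBackend:
    """Base contract: name, unit, overlap guard, raw evaluation.

    ``geometric`` backends interpret the vector as 3-D atomic coordinates
    and are protected by the overlap guard in :func:`evaluate`;
    non-geometric ones (plain objective functions) are not.
    """

    name: str = "abstract"
    unit: str = "model"
    overlap_threshold: float = 0.0
    geometric: bool = True

    def evaluate_raw(self, vec: np.ndarray, tag: str | None = None) -> EnergyResult:
        raise NotImplementedError

    @property
    def has_gradient(self) -> bool:
        return hasattr(self, "gradient")


class LennardJonesBackend(EnergyBackend):
    name = "lennard_jones"

    def __init__(self, params: LennardJonesParams | None = None, **kwargs: float):
        self.params = params or LennardJonesParams(**kwargs)
        # 1e-3*sigma: mathematical-validity guard, not engine protection
        self.overlap_threshold = 1e-3 * self.params.sigma

    def evaluate_raw(self, vec: np.ndarray, tag: str | None = None) -> EnergyResult:
        return EnergyResult("ok", lj_energy(vec, self.params), "model", "lennard_jones")

    def gradient(self, vec: np.ndarray) -> np.ndarray:
        return lj_gradient(vec, self.params)


class MorseBackend(EnergyBackend):
    name = "morse"

    def __init__(self, params: MorseParams | None = None, **kwargs: float):
        self.params = params or MorseParams(**kwargs)
        self.overlap_threshold = 1e-3 * self.params.r_e

    def evaluate_raw(self, vec: np.ndarray, tag: str | None = None) -> EnergyResult:
        return EnergyResult("ok", morse_energy(vec, self.params), "model", "morse")

    def gradient(self, vec: np.ndarray) -> np.ndarray:
        return morse_gradient(vec, self.params)


class FunctionBackend(EnergyBackend):
    """Wrap an arbitrary objective f(vec) -> float as a backend.

    Used for non-geometric test objectives (e.g. the sphere function); the
    overlap guard is disabled.
    """

    name = "function"
    geometric = False

    def __init__(
        self,
        func: Callable[[np.ndarray], float],
        grad: Callable[[np.ndarray], np.ndarray] | None = None,
        name: str = "function",
    ):
        self._func = func
        self._grad = grad
        self.name = name

    def evaluate_raw(self, vec: np.ndarray, tag: str | None = None) -> EnergyResult:
        return EnergyResult("ok", float(self._func(np.asarray(vec, dtype=float))), "model", self.name)

    @property
    def has_gradient(self) -> bool:
        return self._grad is not None

    def gradient(self, vec: np.ndarray) -> np.ndarray:
        if self._grad is None:
            raise AttributeError("no gradient supplied")
        return np.asarray(self._grad(np.asarray(vec, dtype=float)), dtype=float)


# ---------------------------------------------------------------------------
# external-engine coupling
# ---------------------------------------------------------------------------

_PLACEHOLDER_RE = re.compile(r"\{([A-Z_]+)\}")
_KNOWN_PLACEHOLDERS = {"COORDS", "CHARGE", "MULT", "TITLE"}


@dataclass(frozen=True)
class EngineTemplate:
    """Everything needed to couple to an external engine via files.

    ``command`` may contain ``{deck}``, ``{log}`` and ``{dir}`` placeholders,
    substituted per job.  ``energy_pattern`` must capture exactly one real
    number; the *last* match in the log wins (iterative engines append one
    energy per cycle and the converged value is final).
    """

    deck_template: str
    command: str = ""
    energy_pattern: str = r"E\s*=\s*(-?\d+\.\d+)"
    charge: int = 0
    multiplicity: int = 1
    timeout: float = 600.0

    def __post_init__(self) -> None:
        if "{COORDS}" not in self.deck_template:
            raise TemplateError("deck_template must contain the {COORDS} placeholder")
        unknown = set(_PLACEHOLDER_RE.findall(self.deck_template)) - _KNOWN_PLACEHOLDERS
        if unknown:
            raise TemplateError(f"unknown placeholder(s) in deck_template: {sorted(unknown)}")
        if re.compile(self.energy_pattern).groups != 1:
            raise TemplateError("energy_pattern must capture exactly one number")
        if self.multiplicity < 1:
            raise TemplateError("multiplicity must be >= 1")


def render_deck(tmpl: EngineTemplate, geom: ClusterGeometry, title: str = "swarmclust") -> str:
    """Fill the deck template; coordinates printed to 6 decimal places."""
    coord_lines = "\n".join(
        f"{sym} {x:.6f} {y:.6f} {z:.6f}"
        for sym, (x, y, z) in zip(geom.elements, geom.coords)
    )
    mapping = {
        "COORDS": coord_lines,
        "CHARGE": str(tmpl.charge),
        "MULT": str(tmpl.multiplicity),
        "TITLE": title,
    }
    return _PLACEHOLDER_RE.sub(lambda m: mapping[m.group(1)], tmpl.deck_template)


def parse_energy(log_text: str, pattern: str | re.Pattern, unit: str = "hartree") -> EnergyResult:
    """Extract the final energy from an engine log (last match wins)."""
    matches = list(re.finditer(pattern, log_text))
    if not matches:
        tail = log_text[-200:] if log_text else "<empty log>"
        return EnergyResult("engine_failed", PENALTY_ENERGY, unit, f"no energy match; log tail: {tail}")
    value = float(matches[-1].group(1))
    return EnergyResult("ok", value, unit, f"parsed {len(matches)} match(es), last wins")


def _parse_deck_coords(deck_text: str) -> np.ndarray:
    """Read back 'symbol x y z' lines from a rendered deck (mock engine)."""
    rows = []
    for line in deck_text.splitlines():
        parts = line.split()
        if len(parts) == 4:
            try:
                rows.append([float(p) for p in parts[1:]])
            except ValueError:
                continue
    return np.asarray(rows, dtype=float)


_MOCK_DECK = "# {TITLE}\n{CHARGE} {MULT}\n{COORDS}\n"
_MOCK_PATTERN = r"FINAL E\s*=\s*(-?\d+\.\d+)"


class MockEngineBackend(EnergyBackend):
    """In-process stand-in for an external engine.

    Runs the full render -> "invoke" -> parse pipeline: the geometry is
    serialized to a deck (6-decimal rounding), read back, scored with the
    Lennard-Jones potential, written to a log with per-cycle energies, and
    the result is recovered by log parsing.  Optionally persists deck/log
    files under ``scratch_root`` for inspection.
    """

    name = "mock"
    unit = "model"
    overlap_threshold = 0.5  # engine-protection default, as for real engines

    def __init__(
        self,
        params: LennardJonesParams | None = None,
        scratch_root: str | Path | None = None,
        fail_on: Callable[[np.ndarray], bool] | None = None,
        **kwargs: float,
    ):
        self.params = params or LennardJonesParams(**kwargs)
        self.template = EngineTemplate(deck_template=_MOCK_DECK, energy_pattern=_MOCK_PATTERN)
        self.scratch_root = Path(scratch_root) if scratch_root is not None else None
        self._fail_on = fail_on

    def evaluate_raw(self, vec: np.ndarray, tag: str | None = None) -> EnergyResult:
        vec = np.asarray(vec, dtype=float)
        if self._fail_on is not None and self._fail_on(vec):
            return EnergyResult("engine_failed", PENALTY_ENERGY, self.unit, "forced failure")
        n = vec.size // 3
        geom = unflatten(vec, ("X",) * n)
        deck = render_deck(self.template, geom, title=tag or "mock")
        coords = _parse_deck_coords(deck)
        energy = lj_energy(coords.reshape(-1), self.params)
        log = f"mock engine v0\nCYCLE 1 E = {energy + 0.1:.10f}\nFINAL E = {energy:.10f}\n"
        if self.scratch_root is not None and tag is not None:
            jobdir = self.scratch_root / tag
            jobdir.mkdir(parents=True, exist_ok=True)
            (jobdir / "deck.in").write_text(deck)
            (jobdir / "engine.log").write_text(log)
        result = parse_energy(log, self.template.energy_pattern, unit=self.unit)
        return result


class ExternalEngineBackend(EnergyBackend):
    """Couple to any engine runnable as ``command deck -> log`` system call.

    Single-point energies only; no gradients.  Each job runs in its own
    scratch subdirectory (``run_{restart}_{iter}_{particle}`` when driven by
    the search loop), deleted on success and kept on failure.
    """

    name = "external"
    unit = "hartree"
    overlap_threshold = 0.5  # Å; protects the engine from fused nuclei

    def __init__(
        self,
        template: EngineTemplate,
        elements: Sequence[str],
        scratch_root: str | Path = "scratch",
    ):
        if not template.command:
            raise ConfigError("external backend requires a non-empty engine command")
        self.template = template
        self.elements = tuple(elements)
        self.scratch_root = Path(scratch_root)

    def evaluate_raw(self, vec: np.ndarray, tag: str | None = None) -> EnergyResult:
        jobdir = self.scratch_root / (tag or "job")
        jobdir.mkdir(parents=True, exist_ok=True)
        deck_path = jobdir / "deck.in"
        log_path = jobdir / "engine.log"
        geom = unflatten(np.asarray(vec, dtype=float), self.elements)
        deck_path.write_text(render_deck(self.template, geom, title=tag or "job"))
        cmd = [
            part.format(deck=str(deck_path), log=str(log_path), dir=str(jobdir))
            for part in shlex.split(self.template.command)
        ]
        try:
            proc = subprocess.run(
                cmd,
                cwd=jobdir,
                capture_output=True,
                text=True,
                timeout=self.template.timeout,
            )
        except subprocess.TimeoutExpired:
            return EnergyResult(
                "engine_failed", PENALTY_ENERGY, self.unit, f"timeout after {self.template.timeout}s"
            )
        except OSError as exc:
            return EnergyResult("engine_failed", PENALTY_ENERGY, self.unit, f"launch failed: {exc}")
        log_text = log_path.read_text() if log_path.exists() else proc.stdout
        if proc.returncode != 0 and not log_text:
            return EnergyResult(
                "engine_failed", PENALTY_ENERGY, self.unit, f"exit {proc.returncode}: {proc.stderr[-200:]}"
            )
        result = parse_energy(log_text, self.template.energy_pattern, unit=self.unit)
        if result.status == "ok":
            for p in (deck_path, log_path):
                p.unlink(missing_ok=True)
            try:
                jobdir.rmdir()
            except OSError:
                pass
        return result


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_BACKENDS: dict[str, Callable[..., EnergyBackend]] = {
    "lennard_jones": LennardJonesBackend,
    "lj": LennardJonesBackend,
    "morse": MorseBackend,
    "mock": MockEngineBackend,
    "external": ExternalEngineBackend,
}


def make_backend(name: str, **kwargs) -> EnergyBackend:
    """Factory over the registered backend names."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ConfigError(
            f"unknown backend {name!r}; choose from {sorted(set(_BACKENDS))}"
        ) from None
    return cls(**kwargs)


def evaluate(backend: EnergyBackend, vec: Sequence[float], tag: str | None = None) -> EnergyResult:
    """Evaluate one position through the backend contract.

    Near-coincident atoms are rejected *before* touching the backend
    (engine protection); any backend failure is converted to an
    ``engine_failed`` penalty result rather than an exception.
    """
    vec = np.asarray(vec, dtype=float)
    if backend.geometric and backend.overlap_threshold > 0:
        if min_pair_distance(vec) < backend.overlap_threshold:
            return EnergyResult(
                "overlap_rejected",
                PENALTY_ENERGY,
                backend.unit,
                f"min pair distance below {backend.overlap_threshold}",
            )
    try:
        return backend.evaluate_raw(vec, tag=tag)
    except OverlapError as exc:
        return EnergyResult("overlap_rejected", PENALTY_ENERGY, backend.unit, str(exc))
    except Exception as exc:  # noqa: BLE001 - contract: failures become status
        return EnergyResult("engine_failed", PENALTY_ENERGY, backend.unit, repr(exc))
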