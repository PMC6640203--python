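"""File formats, run configuration, geometry fingerprints, the brute-force
reference-minimum oracle, and the command-line interface.

XYZ dialect: line 1 atom count, line 2 free comment, then one
"symbol x y z" line per atom, coordinates in Å.

Run configuration is a TOML document with sections [cluster], exactly one
of [pso]/[sa]/[bh], [backend], optional [executor] and [output].  Every
published swarm parameter is a config default, so the zero-config run
reproduces the reference setup.
"""

from __future__ import annotations

import dataclasses
import math
import sys
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import click
import numpy as np
from scipy.spatial.distance import pdist

from .annealing_hopping import (
    BHConfig,
    CapabilityError,
    SAConfig,
    local_minimize,
    run_bh,
    run_sa,
)
from .cluster_model import (
    ClusterGeometry,
    ConfigError,
    SwarmConfig,
    flatten_geometry,
)
from .energy_backends import (
    EngineTemplate,
    EnergyBackend,
    ExternalEngineBackend,
    make_backend,
)
from .parallel_executor import ExecutorConfig
from .pso_engine import RunResult, restart_search, run_pso

__all__ = [
    "ParseError",
    "OracleConfig",
    "read_xyz",
    "write_xyz",
    "sorted_pair_distances",
    "fingerprints_match",
    "reference_minimum",
    "enumerate_minima",
    "load_run_config",
    "write_trajectory_log",
    "write_summary",
    "cli_run",
    "main",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------


def read_xyz(path: str | Path) -> ClusterGeometry:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"{path} line 1: expected an atom count, got {lines[0]!r}") from None
    if count < 1:
        raise ParseError(f"{path} line 1: atom count must be >= 1")
    if len(lines) < 2 + count:
        raise ParseError(
            f"{path}: header promises {count} atoms but only "
            f"{max(len(lines) - 2, 0)} atom lines follow"
        )
    elements: list[str] = []
    coords: list[list[float]] = []
    for k in range(count):
        lineno = 3 + k
        parts = lines[2 + k].split()
        if len(parts) != 4:
            raise ParseError(f"{path} line {lineno}: expected 'symbol x y z', got {lines[2 + k]!r}")
        try:
            coords.append([float(p) for p in parts[1:]])
        except ValueError:
            raise ParseError(f"{path} line {lineno}: non-numeric coordinate in {lines[2 + k]!r}") from None
        elements.append(parts[0])
    # trailing non-blank lines indicate a count mismatch
    for extra_i, extra in enumerate(lines[2 + count:], start=3 + count):
        if extra.strip():
            raise ParseError(f"{path} line {extra_i}: unexpected extra atom line (header says {count})")
    return ClusterGeometry(tuple(elements), np.asarray(coords))


def read_xyz_comment(path: str | Path) -> str:
    lines = Path(path).read_text().splitlines()
    return lines[1] if len(lines) > 1 else ""


def write_xyz(geom: ClusterGeometry, path: str | Path, comment: str = "") -> None:
    if "\n" in comment:
        raise ParseError("XYZ comment must be a single line")
    out = [str(geom.n_atoms), comment]
    out += [
        f"{sym} {x:.6f} {y:.6f} {z:.6f}"
        for sym, (x, y, z) in zip(geom.elements, geom.coords)
    ]
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# rotation-invariant fingerprints
# ---------------------------------------------------------------------------


def sorted_pair_distances(vec: Sequence[float]) -> np.ndarray:
    """All pairwise distances, ascending: invariant under rigid motion and
    relabeling; empty for fewer than two atoms."""
    coords = np.asarray(vec, dtype=float).reshape(-1, 3)
    if coords.shape[0] < 2:
        return np.empty(0)
    return np.sort(pdist(coords))


def fingerprints_match(
    vec_a: Sequence[float], vec_b: Sequence[float], tol: float = 1e-3
) -> bool:
    """Geometry equivalence test via sorted pair distances (default 1e-3 Å)."""
    fa = sorted_pair_distances(vec_a)
    fb = sorted_pair_distances(vec_b)
    if fa.shape != fb.shape:
        return False
    if fa.size == 0:
        return True
    return bool(np.max(np.abs(fa - fb)) <= tol)


# ---------------------------------------------------------------------------
# brute-force reference-minimum oracle
# ---------------------------------------------------------------------------

ORACLE_MAX_ATOMS = 8


@dataclass(frozen=True)
class OracleConfig:
    n_starts: int = 1000
    seed: int = 0
    init_low: float = -3.0
    init_high: float = 3.0
    minimizer_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ConfigError("n_starts must be >= 1")
        if not self.init_low < self.init_high:
            raise ConfigError("oracle init range is degenerate")


def reference_minimum(
    n_atoms: int,
    potential: EnergyBackend,
    oracle_config: OracleConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Best of many independent local minimizations from uniform random
    starts: a deliberately brute-force, search-independent reference."""
    cfg = oracle_config or OracleConfig()
    if n_atoms > ORACLE_MAX_ATOMS:
        raise CapabilityError(
            f"oracle is desk-scale only (n_atoms <= {ORACLE_MAX_ATOMS}), got {n_atoms}"
        )
    rng = np.random.default_rng(cfg.seed)
    dim = 3 * n_atoms
    best_e = math.inf
    best_x = np.zeros(dim)
    for _ in range(cfg.n_starts):
        x0 = rng.uniform(cfg.init_low, cfg.init_high, size=dim)
        x, e = local_minimize(x0, potential, tol=cfg.minimizer_tol)
        if e < best_e:
            best_e, best_x = e, x
    return best_e, best_x


def enumerate_minima(
    n_atoms: int,
    potential: EnergyBackend,
    oracle_config: OracleConfig | None = None,
    decimals: int = 6,
) -> list[float]:
    """Distinct local-minimum energies (ascending), deduplicated by
    rounding; used to identify the low-lying funnels of small clusters."""
    cfg = oracle_config or OracleConfig()
    if n_atoms > ORACLE_MAX_ATOMS:
        raise CapabilityError(
            f"oracle is desk-scale only (n_atoms <= {ORACLE_MAX_ATOMS}), got {n_atoms}"
        )
    rng = np.random.default_rng(cfg.seed)
    dim = 3 * n_atoms
    found: set[float] = set()
    for _ in range(cfg.n_starts):
        x0 = rng.uniform(cfg.init_low, cfg.init_high, size=dim)
        _, e = local_minimize(x0, potential, tol=cfg.minimizer_tol)
        found.add(round(e, decimals))
    return sorted(found)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_METHODS = ("pso", "sa", "bh")


@dataclass
class RunConfig:
    elements: tuple[str, ...]
    method: str
    backend: EnergyBackend
    pso: SwarmConfig | None = None
    sa: SAConfig | None = None
    bh: BHConfig | None = None
    executor: ExecutorConfig | None = None
    start: ClusterGeometry | None = None
    output_dir: Path = Path(".")
    use_restarts: bool = False


def _build_backend(section: dict, elements: Sequence[str]) -> EnergyBackend:
    section = dict(section)
    name = section.pop("name", None)
    if name is None:
        raise ConfigError("[backend] section requires a 'name' key")
    if name == "external":
        template_path = section.pop("template", None)
        if template_path is None:
            raise ConfigError("[backend] external requires 'template' (path to a TOML engine template)")
        with open(template_path, "rb") as fh:
            tdata = tomllib.load(fh)
        tmpl = EngineTemplate(**tdata)
        return ExternalEngineBackend(tmpl, elements, scratch_root=section.pop("scratch_root", "scratch"))
    return make_backend(name, **section)


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: {exc}") from None

    cluster = data.get("cluster", {})
    start = None
    if "xyz" in cluster:
        xyz_path = Path(cluster["xyz"])
        if not xyz_path.is_absolute():
            xyz_path = path.parent / xyz_path
        start = read_xyz(xyz_path)
        elements = start.elements
    elif "elements" in cluster:
        elements = tuple(cluster["elements"])
    elif "n_atoms" in cluster:
        elements = (cluster.get("element", "C"),) * int(cluster["n_atoms"])
    else:
        raise ConfigError("[cluster] needs 'elements', 'n_atoms' or 'xyz'")

    methods = [m for m in _METHODS if m in data]
    if len(methods) != 1:
        raise ConfigError(
            f"exactly one method section of {_METHODS} must be present, found {methods or 'none'}"
        )
    method = methods[0]

    backend = _build_backend(data.get("backend", {"name": "lennard_jones"}), elements)

    cfg = RunConfig(elements=elements, method=method, backend=backend, start=start)
    section = dict(data[method])
    try:
        if method == "pso":
            cfg.use_restarts = bool(section.pop("restarts", False))
            cfg.pso = SwarmConfig(**section)
        elif method == "sa":
            cfg.sa = SAConfig(**section)
        else:
            cfg.bh = BHConfig(**section)
    except TypeError as exc:
        raise ConfigError(f"[{method}] section: {exc}") from None
    if "executor" in data:
        cfg.executor = ExecutorConfig(**data["executor"])
    cfg.output_dir = Path(data.get("output", {}).get("dir", "."))
    return cfg


# ---------------------------------------------------------------------------
# run artifacts
# ---------------------------------------------------------------------------

_LOG_HEADER = "restart\titeration\tgbest_energy\tevaluations\tstall"


def write_trajectory_log(result: RunResult, path: str | Path) -> None:
    rows = [_LOG_HEADER]
    rows += [
        f"{r}\t{it}\t{e:.10f}\t{ev}\t{stall}" for r, it, e, ev, stall in result.table
    ]
    Path(path).write_text("\n".join(rows) + "\n")


def write_summary(result: RunResult, path: str | Path, seed: int) -> None:
    lines = [
        f"method = {result.method}",
        f"seed = {seed}",
        f"best_energy = {result.best_energy:.10f}",
        f"iterations = {result.iterations_used}",
        f"evaluations = {result.evaluations}",
        f"converged = {result.converged}",
        f"restarts = {result.restarts_used}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _execute(cfg: RunConfig, seed_override: int | None) -> tuple[RunResult, int]:
    n_atoms = len(cfg.elements)
    if cfg.method == "pso":
        pso = cfg.pso or SwarmConfig()
        if seed_override is not None:
            pso = dataclasses.replace(pso, seed=seed_override)
        if cfg.use_restarts:
            result = restart_search(pso, cfg.backend, n_atoms, elements=cfg.elements,
                                    exec_config=cfg.executor)
        else:
            result = run_pso(
                pso,
                cfg.backend,
                n_atoms=None if cfg.start is not None else n_atoms,
                start=cfg.start,
                elements=cfg.elements,
                exec_config=cfg.executor,
            )
        return result, pso.seed
    if cfg.method == "sa":
        sa = cfg.sa or SAConfig()
        if seed_override is not None:
            sa = dataclasses.replace(sa, seed=seed_override)
        start_vec = _start_vector(cfg, sa.seed)
        return run_sa(sa, cfg.backend, start_vec, elements=cfg.elements), sa.seed
    bh = cfg.bh or BHConfig()
    if seed_override is not None:
        bh = dataclasses.replace(bh, seed=seed_override)
    start_vec = _start_vector(cfg, bh.seed)
    return run_bh(bh, cfg.backend, start_vec, elements=cfg.elements), bh.seed


def _start_vector(cfg: RunConfig, seed: int) -> np.ndarray:
    if cfg.start is not None:
        return flatten_geometry(cfg.start)
    rng = np.random.default_rng(seed)
    return rng.uniform(-3.0, 3.0, size=3 * len(cfg.elements))


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
def main() -> None:
    """Global geometry optimization for small atomic clusters."""


@main.command()
@click.option("--config", "config_path", required=True, type=click.Path(), help="TOML run configuration.")
@click.option("--seed", type=int, default=None, help="Override the configured seed.")
@click.option("--out", "out_dir", type=click.Path(), default=None, help="Override the output directory.")
def search(config_path: str, seed: int | None, out_dir: str | None) -> None:
    """Run one search described by a config file."""
    try:
        cfg = load_run_config(config_path)
    except FileNotFoundError as exc:
        raise click.UsageError(f"config file not found: {exc}")
    except (ConfigError, ParseError) as exc:
        raise click.UsageError(str(exc))
    outdir = Path(out_dir) if out_dir is not None else cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        result, used_seed = _execute(cfg, seed)
    except (CapabilityError, ConfigError) as exc:
        raise click.ClickException(str(exc))
    write_xyz(
        result.best_geometry,
        outdir / "best.xyz",
        comment=f"method={result.method} energy={result.best_energy:.10f}",
    )
    write_trajectory_log(result, outdir / "trajectory.log")
    write_summary(result, outdir / "summary.txt", used_seed)
    click.echo(
        f"{result.method}: best energy {result.best_energy:.6f} "
        f"after {result.iterations_used} iterations "
        f"({'converged' if result.converged else 'not converged'})"
    )


@main.command()
@click.option("--atoms", "n_atoms", required=True, type=int)
@click.option("--backend", "backend_name", default="lennard_jones", show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", type=click.Path(), default=None)
@click.option("--max-iter", type=int, default=300, show_default=True)
def compare(n_atoms: int, backend_name: str, seed: int, out_dir: str | None, max_iter: int) -> None:
    """Run the swarm, annealing, and hopping searchers on one system and
    print a comparison table (method, iterations, best energy, converged)."""
    try:
        backend = make_backend(backend_name)
    except ConfigError as exc:
        raise click.UsageError(str(exc))
    rng = np.random.default_rng(seed)
    start = rng.uniform(-3.0, 3.0, size=3 * n_atoms)
    results = [
        run_pso(SwarmConfig(seed=seed, max_iter=max_iter), backend, n_atoms=n_atoms),
        run_sa(SAConfig(seed=seed), backend, start),
        run_bh(BHConfig(seed=seed), backend, start),
    ]
    rows = ["method\titerations\tbest_energy\tconverged"]
    for r in results:
        rows.append(f"{r.method}\t{r.iterations_used}\t{r.best_energy:.6f}\t{r.converged}")
    report = "\n".join(rows)
    click.echo(report)
    if out_dir is not None:
        outdir = Path(out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "compare.tsv").write_text(report + "\n")
        for r in results:
            write_trajectory_log(r, outdir / f"trajectory_{r.method}.log")


@main.command()
@click.option("--atoms", "n_atoms", required=True, type=int)
@click.option("--potential", default="lennard_jones", show_default=True)
@click.option("--starts", type=int, default=1000, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_path", type=click.Path(), default=None, help="Write the minimum as XYZ.")
def oracle(n_atoms: int, potential: str, starts: int, seed: int, out_path: str | None) -> None:
    """Brute-force reference minimum via multi-start local minimization."""
    try:
        backend = make_backend(potential)
        energy, vec = reference_minimum(
            n_atoms, backend, OracleConfig(n_starts=starts, seed=seed)
        )
    except (ConfigError, CapabilityError) as exc:
        raise click.ClickException(str(exc))
    click.echo(f"reference minimum for n={n_atoms} ({backend.name}): {energy:.8f}")
    if out_path is not None:
        geom = ClusterGeometry(("C",) * n_atoms, vec.reshape(-1, 3))
        write_xyz(geom, out_path, comment=f"oracle minimum {energy:.8f}")


def cli_run(argv: Sequence[str]) -> int:
    """Programmatic CLI entry point; returns the exit status instead of
    raising SystemExit (0 success, 1 runtime failure, 2 invalid usage)."""
    try:
        main.main(args=list(argv), prog_name="swarmclust", standalone_mode=False)
    except click.UsageError as exc:
        click.echo(f"error: {exc.format_message()}", err=True)
        return 2
    except click.ClickException as exc:
        click.echo(f"error: {exc.format_message()}", err=True)
        return 1
    except SystemExit as exc:  # --help and friends
        code = exc.code if isinstance(exc.code, int) else 0
        return code
    except (ConfigError, ParseError) as exc:
        click.echo(f"error: {exc}", err=True)
        return 2
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        click.echo(f"runtime failure: {exc}", err=True)
        return 1
    return 0


if __name__ == "__main__":
    sys.exit(cli_run(sys.argv[1:]))
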