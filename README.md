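# swarmclust

Swarm-based global geometry optimization for small atomic clusters, with
simulated-annealing and basin-hopping comparators, a pluggable
energy-backend contract, and barrier-synchronized parallel energy
evaluation.

A cluster of *n* atoms is encoded as a flat 3*n* vector (atom *i* in slots
3*i*..3*i*+2). A swarm of such vectors moves under inertia plus attraction
toward each particle's personal best and the global best:

```
v' = w*v + d1*eps1*(pbest - x) + d2*eps2*(gbest - x)
x' = x + v'
```

with the inertia weight descending linearly from 0.8 to 0.4, both
acceleration coefficients set to 2, population 10, and random structures
initialized in (−3, 3) per coordinate. A run terminates when the global
best energy is flat for 30 consecutive iterations; an outer restart loop
re-seeds swarms from the incumbent best until two consecutive restarts
agree ("self-consistency"). Energies come from a backend: built-in
Lennard-Jones / Morse pair potentials for desk-scale work, or any external
quantum-chemistry engine invoked as a system call through a text
input-deck template and a log-parsing pattern.

## Library quick start

```python
from swarmclust import SwarmConfig, make_backend, run_pso, restart_search

backend = make_backend("lennard_jones")           # eps = sigma = 1
result = run_pso(SwarmConfig(seed=0), backend, n_atoms=3)
print(result.best_energy)                          # ~ -3.0 (equilateral triangle)

result = restart_search(SwarmConfig(seed=0, n_restarts=4), backend, n_atoms=6)
```

Comparators over the same backend contract:

```python
from swarmclust import SAConfig, BHConfig, run_sa, run_bh
import numpy as np

start = np.random.default_rng(0).uniform(-1.2, 1.2, 9)
run_sa(SAConfig(seed=0), backend, start)           # Metropolis walk, slow cooling
run_bh(BHConfig(seed=0), backend, start)           # perturb -> minimize -> accept
```

## CLI

```
swarmclust search  --config run.toml [--seed N] [--out DIR]
swarmclust compare --atoms 5 --seed 0 --out DIR
swarmclust oracle  --atoms 5 --starts 1000 --seed 0
```

`search` writes `best.xyz`, a tab-separated `trajectory.log`
(restart / iteration / gbest energy / evaluations / stall counter) and a
`summary.txt`. `compare` runs the swarm, annealing, and hopping searchers
on one system and emits a table (method, iterations, best energy,
converged). `oracle` computes a brute-force reference minimum by
multi-start local minimization (n ≤ 8).

A run configuration is TOML with `[cluster]`, exactly one of
`[pso]`/`[sa]`/`[bh]`, `[backend]`, and optional `[executor]`/`[output]`
sections; see `examples/lj3.toml`. Every swarm parameter above is a config
default, so the zero-config run reproduces the reference setup.

### External engines

An engine is described entirely by a template (no engine-specific code):

```toml
# examples/engine_template.example.toml — Gaussian-style single point
deck_template = """%NProcShared=2
#P B3LYP/6-311+G* SP

{TITLE}

{CHARGE} {MULT}
{COORDS}

"""
command = "g09 {deck} {log}"
energy_pattern = 'SCF Done:\s+E\(\S+\)\s+=\s+(-?\d+\.\d+)'
charge = 0
multiplicity = 1
timeout = 3600.0
```

`{COORDS}` becomes one `symbol x y z` line per atom (6 decimals); the
*last* `energy_pattern` match in the log wins. Evaluations that place
atoms closer than 0.5 Å are rejected before the engine is invoked, and
failed or timed-out jobs score a +1e6 penalty instead of aborting the
iteration barrier. Each job runs in its own scratch subdirectory
(`run_{restart}_{iter}_{particle}`), removed on success.

## Parallelism & determinism

`ExecutorConfig(n_workers=...)` evaluates the swarm with one job per
particle and a barrier at iteration end. All randomness is drawn from
per-particle substreams in the coordinator before dispatch, so a fixed
seed produces bit-identical trajectories for any worker count.

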