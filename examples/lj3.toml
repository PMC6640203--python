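# Three-atom Lennard-Jones search with the reference swarm parameters.
# Run:  swarmclust search --config examples/lj3.toml --out out/

[cluster]
elements = ["C", "C", "C"]

[pso]
seed = 0
max_iter = 200
# restarts = true        # enable the outer self-consistency loop

[backend]
name = "lennard_jones"
epsilon = 1.0
sigma = 1.0

[executor]
n_workers = 1

[output]
dir = "out"
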