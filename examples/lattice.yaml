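# Reference 101-level comparison: w=0.5 open system, positive drift,
# linear potential steep enough that the quantum packet oscillates in
# roughly [0.5, 0.75] of the evidence scale.
model:
  n_levels: 101
  alpha: 10.0
  beta: 11.0
  w: 0.5
  coupling: {kind: generator}
  hamiltonian: {a: 0.0, b: 16.0, c: 0.0, sigma: 1.0}
initial: {kind: gaussian, center: 50, std: 10.0}
schedule: {t_start: 0.0, t_stop: 120.0, n_points: 121}
output: {directory: out/lattice}
seed: 1
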