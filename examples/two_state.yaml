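# Two-level example with closed-form equilibria at w=0.5:
# G=K  -> diag (1/3, 2/3), coherence 1/3
# G=T(inf) -> diag (4/9, 5/9), coherence (1+i)/18
model:
  n_levels: 2
  alpha: 1.0
  beta: 2.0
  w: 0.5
  coupling: {kind: generator}
  hamiltonian: {a: 0.0, b: 1.0, c: 0.0, sigma: 1.0}
initial: {kind: delta, level: 0}
schedule: {t_start: 0.0, t_stop: 30.0, n_points: 61}
output: {directory: out/two_state}
seed: 1
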