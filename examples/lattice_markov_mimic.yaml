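# Full dissipation (w=1) with the scaled transition coupling T(tau)/tau at
# tau=1e-3: approximates the pure Markov walk while keeping every Lindblad
# rate nonnegative. Coherences die at rate 1/tau.
model:
  n_levels: 101
  alpha: 10.0
  beta: 11.0
  w: 1.0
  coupling: {kind: scaled_transition, tau: 0.001}
  hamiltonian: {a: 0.0, b: 16.0, c: 0.0, sigma: 1.0}
initial: {kind: gaussian, center: 50, std: 10.0}
schedule: {t_start: 0.0, t_stop: 120.0, n_points: 121}
output: {directory: out/mimic}
seed: 1
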