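# Methods

## Model and conventions

The package simulates evidence/preference accumulation on a discrete
lattice of `N` levels. Level `j` (0-based everywhere; narrative accounts
that speak of "row 66" for level 65 are counting from 1) carries the
likelihood value `x_j = j/(N−1)`.

**Markov component.** The classical accumulator is a continuous-time
birth–death chain with upward rate `β`, downward rate `α`, and reflecting
bounds: intensity matrix `K` with sub-diagonal `β`, super-diagonal `α`,
interior diagonal `−(α+β)`, corner diagonals `−β` and `−α`. Columns sum
to zero; with both rates positive the chain is irreducible and its unique
stationary law is the detailed-balance profile `φ*_j ∝ (β/α)^j`. Drift
and diffusion are `μ = (β−α)/2` and `σ² = (β+α)/2`; `β` is the rate
toward *higher* evidence, fixed by requiring positive drift to push the
distribution rightward.

**Quantum component.** The Hamiltonian is tridiagonal: constant hopping
`σ` off the diagonal, and on the diagonal the potential
`μ(x) = a + bx + cx²` evaluated at the level values `x_j` (dimensionless;
the potential is defined on the same [0, 1] axis as the mean-evidence
summaries). `U(t) = exp(−iHt)` is evaluated through the cached Hermitian
eigendecomposition, so a whole time grid costs one diagonalisation.

**Open system.** The master equation

    dρ/dt = −i(1−w)[H, ρ] + w Σ_ij γ_ij (L_ij ρ L_ij† − ½{L_ij†L_ij, ρ})

uses the fixed jump basis `L_ij = |i⟩⟨j|` (transition to level i from
level j). For this basis the dissipator reduces exactly, with
`d = diag(ρ)` and column sums `c_k = Σ_i γ_ik`, to

* diagonal: `(G d)_k − c_k d_k` — a classical master equation in the
  level populations;
* off-diagonal: `−½(c_k + c_l) ρ_kl` — coherence damping.

The implementation evaluates this closed form (O(N²) per application)
rather than summing N² operator sandwiches; the brute-force sum is kept
in the test suite as an independent oracle. Note the off-diagonal law is
`−½(c_k + c_l) ρ_kl` in general; it collapses to the familiar
`−ρ_kl · Σ_i γ_ik` exactly when the column sums are constant, which holds
for all three shipped coupling recipes.

**Coupling recipes.** `G = K` makes the diagonal flow exactly the Markov
walk and leaves coherences untouched (`c = 0`). `G = T(τ) = exp(Kτ)`
damps every coherence at rate `w` and drives the populations by
`(T(τ) − I)`, i.e. the same distributions as the `(T(τ)−I)/τ` Markov flow
on a clock slower by `1/τ`. `G = T(τ)/τ` approximates the `G = K`
diagonal flow as `τ → 0` while damping coherences at rate `1/τ`.
`τ = ∞` is accepted for the transition recipe and uses the equilibrium
transition matrix (every column the stationary law) — the regime in which
the two-state equilibrium has a closed form.

**Complete positivity of G.** In the fixed basis `L_ij = |i⟩⟨j|` the GKSL
coefficient matrix over jump operators is *diagonal* with entries
`γ_ij`, so the dissipator is completely positive exactly when every
`γ_ij ≥ 0`. The `is_positive` diagnosis on a coupling is therefore an
entrywise check (tolerance 1e−10). `T(τ)` qualifies; `K` does not (its
diagonal rates are negative), and the propagator accordingly treats a
negative density eigenvalue as an error under a CP coupling but as a
reportable `PositivityWarning` under `G = K`. This mirrors the practical
advice to try `G = K` and watch whether the density misbehaves: the
package reports physicality rather than legislating it.

**Vectorisation.** Superoperators act on column-stacked densities
(`vec(ρ)` in Fortran order), using `vec(XYZ) = (Zᵀ ⊗ X) vec(Y)` with the
plain (unconjugated) transpose. The assembled generator is

    𝓛 = −i(1−w)(I⊗H − Hᵀ⊗I) + w [ Σ γ_ij E_ij⊗E_ij − ½(I⊗C + C⊗I) ],

`C = diag(c)`; the jump sum only couples the N diagonal vec-slots, so the
sparse assembly is O(N²) nonzeros. Trace preservation (the de-vectorised
action of 𝓛 is traceless) is exact by construction and asserted to 1e−10.

## Solvers and numerical choices

* **Propagation.** Dense `expm(t𝓛)` for `N ≤ 32`; sparse
  `expm_multiply` action above that (the 101-level lattice gives a
  10 201-dimensional vectorised state, comfortably within the sparse
  path). An independent route integrates the closed-form right-hand side
  with DOP853 at `rtol = 1e−9`, `atol = 1e−11`; the two routes are
  required to agree to 1e−6 elementwise and disagreement is treated as an
  assembly bug, not tolerated.
* **Contracts.** After every propagation: `|Tr ρ − 1| < 1e−8`,
  Hermiticity deviation `< 1e−8` (then symmetrised), minimum eigenvalue
  `≥ −1e−8` unless the coupling is non-CP, in which case the violation is
  warned about and the state flagged `allow_nonpositive`.
* **Equilibria.** For `N ≤ 32`: dense SVD null space of 𝓛; a stationary
  set of dimension ≠ 1 is reported (warning with the dimension) and
  `None` returned — the pure quantum flow (`w = 0`), whose stationary set
  is every density commuting with H, is the canonical degenerate case.
  The Hermitian trace-1 representative is extracted by symmetrising the
  null vector and normalising its trace. For larger `N` the singular
  system is solved directly with the trace functional replacing one row,
  then verified against the residual `‖𝓛 vec(ρ*)‖`.
* **State validation tolerances.** Probability/amplitude normalisation
  1e−12, density Hermiticity/trace 1e−10, eigenvalue floor −1e−8. These
  are package constants in `openwalk.state_space`.
* **Sequential measurement.** Joint response probabilities chain
  *unnormalised* Lüders projections `ρ → M ρ M` between propagation
  segments; the final trace (or squared norm, for amplitudes) is the
  joint probability. Renormalisation happens only when a conditional
  post-measurement state is explicitly requested. Measurement times must
  be strictly increasing.

## The two-state example

With `H = [[0,1],[1,1]]` — the lattice Hamiltonian with `b = σ = 1`
evaluated on levels {0, 1} — and `K = [[−β, α],[β, −α]]` at `w = 0.5`,
the stationary conditions solve in closed form:

* `G = K`: `ρ*₁₁ = α/(α+β)`, `ρ*₂₂ = β/(α+β)`,
  `ρ*₂₁ = (β−α)/(α+β)` — the Markov asymptote, reached in a *coherent*
  state. It is PSD iff `αβ ≥ (β−α)²`; outside that region the model
  converges to an indefinite "density", which the package reports rather
  than hides.
* `G = T(∞)`: `ρ*₁₁ = (1/3)(1 + α/(α+β))`,
  `ρ*₂₂ = (1/3)(1 + β/(α+β))`, `ρ*₂₁ = ((1+i)/6)(1 − 2α/(α+β))` — the
  "yes" probability settles strictly below the Markov asymptote.

These are re-derived in the test suite and recovered both by the
null-space solver and by integrating to `t = 100` (tolerance 1e−6). Note
the diagonal-potential term in H is essential: with the zero-potential
`[[0,1],[1,0]]` the coherence along the coupling axis commutes with H and
the stationary set degenerates.

## Reference lattice conditions

The 101-level comparison runs four models — pure Markov, pure quantum,
open with `G=K`, open with `G=T(1)` — from a discrete Gaussian initial
distribution (the quantum/open models take its square root as the initial
amplitude). The published account of this comparison does not print its
parameter values, so the package declares its own reference conditions
once: `α = 10`, `β = 11` (drift 0.5, Markov invariant mean ≈ 0.900),
`b = 16`, `σ = 1` (quantum mean oscillates in ≈ [0.50, 0.75], with a
lattice Bloch period `2π(N−1)/b ≈ 39` time units), Gaussian centre 50,
standard deviation 10 (= N/10, the default when unspecified), `w = 0.5`,
`τ = 1`, and `τ = 10⁻³` for the full-dissipation Markov mimic. All
assertions about this configuration are shape and limit checks (monotone
vs oscillatory, equal vs lower equilibria), never figure-read values.

**Slow coherence relaxation under `G = K`.** Because `G = K` leaves
coherences undamped at the dissipator level, their relaxation is an
indirect, second-order effect of the Hamiltonian coupling into the
damped populations. On the 101-level lattice this makes the approach to
equilibrium extremely slow: a steep potential Stark-localises the
Hamiltonian eigenstates and the surviving coherence modes are undamped to
numerical precision, so a finite-horizon trajectory of the mean hovers
within about 1e−2 of its limit indefinitely rather than converging
further. The *limit itself* is sharp: the unique stationary state of the
`w = 0.5`, `G = K` flow has diagonal equal to the Markov invariant law to
~1e−13, and the package's checks compare limits via the stationary-state
solver while asserting the qualitative trajectory shapes on finite grids.
The `G = T(1)` flow, whose coherences are genuinely damped, converges at
rate ~`w` and its equilibrium mean sits strictly below the Markov mean
(≈ 0.880 vs 0.900 under the reference conditions).

## Synthetic data and weight recovery

The paradigm generator emulates the two-condition choice/confidence
design: in the choice–confidence condition a complete binary choice
measurement at `t1` (Lüders collapse) precedes a complete confidence
measurement at `t2`; in the confidence-alone condition only `t2` is
measured. Confidence outcomes are a partition of the lattice into
contiguous bins (default 21 bins for N=101; single-level bins for N=2) —
a package convention, since applications differ on how ratings map to
projectors. Trials are i.i.d. multinomial draws from the model's *exact*
outcome probabilities under a seeded generator.

`fit_weight` maximises the multinomial log-likelihood over `w ∈ [0, 1]`
on a 0.01 grid followed by bounded scalar refinement between the
neighbouring grid points; likelihoods come from exact model
probabilities, so the fit is deterministic given data. A profile whose
spread is below 1e−6 log-units is flagged `flat` instead of returning an
arbitrary argmax. The shipped recovery study uses the two-state family
(`α=1, β=2`, `G=K`, initial state |0⟩⟨0|) measured at `t1 = 0.5`,
`t2 = 1.0` — order-one times at which both the quantum oscillation and
the dissipative drift have acted, which a short pre-study of the
likelihood curvature showed to identify `w` well. At 10⁴ trials per
condition the estimate lands within a few hundredths of the generating
value.

What the synthetic generator does *not* emulate: response times (no
absorbing boundaries / first-passage machinery), trial-to-trial parameter
drift, lapses, or any stimulus model. Passing recovery tests therefore
show that `w` is identifiable from idealised paradigm frequencies at
these sample sizes — not that it is identifiable from any particular real
dataset.

## Known limitations

* `G = K` yields a non-CP flow: densities can and do leave the PSD cone
  (reported, never silently repaired), and convergence to equilibrium can
  be arbitrarily slow on large lattices (see above).
* The equilibrium solver returns `None` for degenerate stationary sets
  rather than selecting a member; degeneracy detection above `N = 32`
  relies on the residual check of the direct solve, not an exact
  null-space dimension.
* Time-independent `H` and `G` only; no system-plus-environment
  derivation, no non-Markovian memory kernels, no coin-based
  discrete-time quantum walks.
* Dense matrix exponentials are used for generators up to `N = 512`
  (Markov) and vectorised dimension 32² (open system); nothing in the
  package is tuned for lattices beyond a few hundred levels.
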