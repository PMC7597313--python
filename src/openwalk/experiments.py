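"""Reference experiments: trajectories, interference, and weight recovery.

This module packages the model comparisons that motivate the open-system
framework:

* the two-state example with its closed-form equilibria
  (:func:`two_state_trajectory`);
* the 101-level lattice comparison of the four models -- pure Markov,
  pure quantum, open system with G=K and with G=T(tau)
  (:func:`evidence_trajectory`);
* the choice-confidence interference paradigm: measuring a choice at an
  intermediate time changes the later confidence distribution for quantum
  dynamics but not for Markov dynamics (:func:`interference_statistic`);
* synthetic behavioural data sampled from a model's exact outcome
  probabilities, and maximum-likelihood recovery of the mixing weight w
  from such data (:func:`generate_synthetic_dataset`, :func:`fit_weight`).

The two-state example uses the Hamiltonian ``[[0, 1], [1, 1]]`` -- the
tridiagonal lattice Hamiltonian with linear potential slope b=1 and
coupling sigma=1 evaluated on the two level values {0, 1} -- together
with the generator ``[[-beta, alpha], [beta, -alpha]]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .markov_walk import (
    MarkovGenerator,
    invariant_distribution,
    tridiagonal_generator,
)
from .open_system import (
    LindbladCoupling,
    OpenSystemModel,
    build_superoperator,
    coupling_from_generator,
    coupling_from_scaled_transition,
    coupling_from_transition,
    equilibrium,
    propagate_density_grid,
)
from .quantum_walk import Hamiltonian, tridiagonal_hamiltonian, unitary
from .state_space import (
    AmplitudeState,
    DensityState,
    EvidenceScale,
    ProbabilityState,
    ResponseProjector,
    make_gaussian_probability,
    mean_evidence,
    probability_to_amplitude,
    projector_for_levels,
    pure_density,
)

__all__ = [
    "ParadigmDesign",
    "SyntheticDataset",
    "WeightFamily",
    "WeightFit",
    "InterferenceResult",
    "EvidenceTrajectories",
    "binary_choice_projectors",
    "confidence_bin_projectors",
    "two_state_model",
    "two_state_trajectory",
    "evidence_trajectory",
    "outcome_probabilities",
    "interference_statistic",
    "generate_synthetic_dataset",
    "fit_weight",
]

ModelLike = Union[MarkovGenerator, Hamiltonian, OpenSystemModel]
StateLike = Union[ProbabilityState, AmplitudeState, DensityState]


# ---------------------------------------------------------------------------
# designs

@dataclass
class ParadigmDesign:
    """A two-stage measurement design: choice at t1, confidence at t2.

    Both projector families must partition the lattice (sum to the
    identity), so each stage is a complete measurement and outcome
    probabilities sum to one.
    """

    t1: float
    t2: float
    choice_projectors: List[ResponseProjector]
    confidence_projectors: List[ResponseProjector]

    def __post_init__(self) -> None:
        if not 0 < self.t1 < self.t2:
            raise ValueError("need 0 < t1 < t2")
        for name, fam in (
            ("choice", self.choice_projectors),
            ("confidence", self.confidence_projectors),
        ):
            n = fam[0].n_levels
            covered = sorted(j for M in fam for j in M.levels)
            if covered != list(range(n)):
                raise ValueError(
                    f"{name} projectors must partition the lattice exactly once"
                )

    @property
    def n_levels(self) -> int:
        return self.choice_projectors[0].n_levels


def binary_choice_projectors(scale: EvidenceScale) -> List[ResponseProjector]:
    """'No' on the lower half, 'yes' strictly above the midpoint.

    For an odd lattice the equivocal midpoint level is assigned to 'no',
    mirroring the convention that 'yes' spans the strictly-favouring
    levels.
    """
    n = scale.n_levels
    cut = n // 2
    return [
        projector_for_levels(scale, range(0, cut + n % 2), label="no"),
        projector_for_levels(scale, range(cut + n % 2, n), label="yes"),
    ]


def confidence_bin_projectors(
    scale: EvidenceScale, n_bins: int = 21
) -> List[ResponseProjector]:
    """Partition the lattice into contiguous confidence-rating bins."""
    n = scale.n_levels
    if not 1 <= n_bins <= n:
        raise ValueError("bin count must lie in 1..N")
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    return [
        projector_for_levels(scale, range(lo, hi), label=f"conf_{k}")
        for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]))
    ]


# ---------------------------------------------------------------------------
# generic two-stage propagation

def _markov_step(K: MarkovGenerator, vec: np.ndarray, dt: float) -> np.ndarray:
    return expm(K.matrix * dt) @ vec


def _open_stepper(model: OpenSystemModel):
    L = build_superoperator(model, sparse=model.n_levels > 32).matrix
    n = model.n_levels

    def step(mat: np.ndarray, dt: float) -> np.ndarray:
        v = mat.reshape(-1, order="F")
        if model.n_levels > 32:
            from scipy.sparse.linalg import expm_multiply

            v = expm_multiply(L * dt, v)
        else:
            v = expm(L * dt) @ v
        return v.reshape((n, n), order="F")

    return step


def _density_of(state: StateLike) -> np.ndarray:
    if isinstance(state, DensityState):
        return state.matrix.copy()
    if isinstance(state, AmplitudeState):
        return np.outer(state.amps, state.amps.conj())
    raise TypeError(f"cannot form a density from {type(state)}")


def outcome_probabilities(
    model: ModelLike,
    state0: StateLike,
    design: ParadigmDesign,
    condition: str,
) -> np.ndarray:
    """Exact outcome probabilities for one condition of the paradigm.

    ``choice_confidence`` returns the joint matrix p(choice i at t1,
    confidence k at t2) of shape (n_choice, n_conf); ``confidence_alone``
    returns the marginal confidence distribution p(confidence k at t2)
    with no intermediate measurement.  Intermediate branches are the
    unnormalised Lueders projections, so the joint matrix sums to one.
    """
    if condition not in ("choice_confidence", "confidence_alone"):
        raise ValueError(f"unknown condition {condition!r}")
    nC = len(design.choice_projectors)
    nF = len(design.confidence_projectors)

    if isinstance(model, MarkovGenerator):
        if not isinstance(state0, ProbabilityState):
            raise TypeError("Markov dynamics need a ProbabilityState")
        v1 = _markov_step(model, state0.probs, design.t1)
        if condition == "confidence_alone":
            v2 = _markov_step(model, v1, design.t2 - design.t1)
            return np.array(
                [v2[list(M.levels)].sum() for M in design.confidence_projectors]
            )
        out = np.zeros((nC, nF))
        for i, Mc in enumerate(design.choice_projectors):
            branch = _markov_step(model, Mc.apply_vector(v1), design.t2 - design.t1)
            out[i] = [branch[list(M.levels)].sum() for M in design.confidence_projectors]
        return out

    if isinstance(model, Hamiltonian):
        rho1 = _density_of(state0)
        u1 = unitary(model, design.t1)
        u2 = unitary(model, design.t2 - design.t1)
        rho1 = u1 @ rho1 @ u1.conj().T
        if condition == "confidence_alone":
            rho2 = u2 @ rho1 @ u2.conj().T
            d = np.real(np.diag(rho2))
            return np.array(
                [d[list(M.levels)].sum() for M in design.confidence_projectors]
            )
        out = np.zeros((nC, nF))
        for i, Mc in enumerate(design.choice_projectors):
            branch = u2 @ Mc.sandwich(rho1) @ u2.conj().T
            d = np.real(np.diag(branch))
            out[i] = [d[list(M.levels)].sum() for M in design.confidence_projectors]
        return out

    if isinstance(model, OpenSystemModel):
        step = _open_stepper(model)
        rho1 = step(_density_of(state0), design.t1)
        if condition == "confidence_alone":
            d = np.real(np.diag(step(rho1, design.t2 - design.t1)))
            return np.array(
                [d[list(M.levels)].sum() for M in design.confidence_projectors]
            )
        out = np.zeros((nC, nF))
        for i, Mc in enumerate(design.choice_projectors):
            branch = step(Mc.sandwich(rho1), design.t2 - design.t1)
            d = np.real(np.diag(branch))
            out[i] = [d[list(M.levels)].sum() for M in design.confidence_projectors]
        return out

    raise TypeError(f"unsupported model type {type(model)}")


# ---------------------------------------------------------------------------
# interference

@dataclass
class InterferenceResult:
    """Confidence distributions with and without a recorded choice."""

    pooled: np.ndarray       # choice measured at t1, outcomes pooled
    unmeasured: np.ndarray   # no measurement at t1
    l1_distance: float

    def __iter__(self):
        return iter((self.pooled, self.unmeasured, self.l1_distance))


def interference_statistic(
    model: ModelLike, state0: StateLike, design: ParadigmDesign
) -> InterferenceResult:
    """Chapman-Kolmogorov discrepancy between the paradigm's conditions.

    Compares the confidence distribution at t2 pooled over the (recorded
    but marginalised) choice outcomes at t1 with the distribution when no
    choice is measured.  Markov dynamics -- and any Markov-reducible open
    system -- make these identical; quantum collapse at t1 makes them
    differ.  Returns both distributions and their L1 distance.
    """
    joint = outcome_probabilities(model, state0, design, "choice_confidence")
    pooled = joint.sum(axis=0)
    unmeasured = outcome_probabilities(model, state0, design, "confidence_alone")
    return InterferenceResult(pooled, unmeasured, float(np.abs(pooled - unmeasured).sum()))


# ---------------------------------------------------------------------------
# synthetic data and weight recovery

@dataclass
class SyntheticDataset:
    """Multinomial draws from a model's exact paradigm probabilities.

    ``trials`` holds per-trial outcomes: columns (choice, confidence) for
    the choice-confidence condition with choice = -1 in the
    confidence-alone condition.  ``counts`` is the outcome contingency
    table (choice x confidence, or a confidence vector).
    """

    condition: str
    trials: np.ndarray
    counts: np.ndarray
    seed: Optional[int] = None

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


def generate_synthetic_dataset(
    model: ModelLike,
    state0: StateLike,
    design: ParadigmDesign,
    n_trials: int,
    condition: str,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SyntheticDataset:
    """Sample ``n_trials`` paradigm outcomes from the exact probabilities."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if rng is None:
        rng = np.random.default_rng(seed)
    probs = outcome_probabilities(model, state0, design, condition)
    flat = probs.flatten()
    flat = np.clip(flat, 0.0, None)
    flat = flat / flat.sum()
    draws = rng.choice(flat.size, size=n_trials, p=flat)
    counts = np.bincount(draws, minlength=flat.size).reshape(probs.shape)
    if condition == "choice_confidence":
        nF = len(design.confidence_projectors)
        trials = np.column_stack([draws // nF, draws % nF])
    else:
        trials = np.column_stack([np.full(n_trials, -1), draws])
    return SyntheticDataset(condition, trials, counts, seed=seed)


@dataclass
class WeightFamily:
    """Open-system model family with unknown mixing weight w.

    Everything but w is fixed: the Hamiltonian, the Markov generator, the
    coupling recipe (kind and tau), the initial state, and the paradigm
    design.  ``model(w)`` instantiates a member.
    """

    hamiltonian: Hamiltonian
    generator: MarkovGenerator
    coupling_kind: str
    design: ParadigmDesign
    state0: DensityState
    tau: float = 1.0
    _coupling: LindbladCoupling = field(default=None, repr=False, compare=False)

    def coupling(self) -> LindbladCoupling:
        if self._coupling is None:
            builders = {
                "generator": lambda: coupling_from_generator(self.generator),
                "transition": lambda: coupling_from_transition(self.generator, self.tau),
                "scaled_transition": lambda: coupling_from_scaled_transition(
                    self.generator, self.tau
                ),
            }
            self._coupling = builders[self.coupling_kind]()
        return self._coupling

    def model(self, w: float) -> OpenSystemModel:
        return OpenSystemModel(self.hamiltonian, self.coupling(), w)


@dataclass
class WeightFit:
    """Maximum-likelihood estimate of w with its profile."""

    w_hat: float
    grid: np.ndarray
    log_likelihood: np.ndarray
    flat: bool = False

    @property
    def max_log_likelihood(self) -> float:
        return float(self.log_likelihood.max())


def _dataset_loglik(family: WeightFamily, w: float, datasets) -> float:
    ll = 0.0
    model = family.model(w)
    for ds in datasets:
        probs = outcome_probabilities(
            model, family.state0, family.design, ds.condition
        ).flatten()
        counts = ds.counts.flatten()
        if probs.shape != counts.shape:
            raise ValueError("dataset outcomes inconsistent with the design")
        ll += float(counts @ np.log(np.clip(probs, 1e-300, None)))
    return ll


def fit_weight(
    datasets: Sequence[SyntheticDataset],
    family: WeightFamily,
    grid: Optional[np.ndarray] = None,
    refine: bool = True,
) -> WeightFit:
    """Maximum-likelihood w in [0, 1] by dense grid search plus refinement.

    The likelihood is multinomial with outcome probabilities computed
    exactly from the model, so the fit is deterministic given the data.
    A flat profile (spread below ~1e-6 log-units) is reported via the
    ``flat`` flag rather than guessed over.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    ll = np.array([_dataset_loglik(family, w, datasets) for w in grid])
    flat = bool(ll.max() - ll.min() < 1e-6)
    i = int(np.argmax(ll))
    w_hat = float(grid[i])
    if refine and not flat:
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda w: -_dataset_loglik(family, w, datasets),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-5},
            )
            if res.success and -res.fun >= ll[i] - 1e-12:
                w_hat = float(res.x)
    return WeightFit(w_hat, grid, ll, flat=flat)


# ---------------------------------------------------------------------------
# the two reference examples

def two_state_model(
    alpha: float,
    beta: float,
    w: float,
    coupling_kind: str = "generator",
    tau: float = np.inf,
) -> OpenSystemModel:
    """Two-level open system: H=[[0,1],[1,1]], K=[[-beta,alpha],[beta,-alpha]].

    The Hamiltonian is the lattice form with linear potential slope 1 and
    coupling 1 on the two level values {0, 1}.  The default transition
    coupling uses tau = inf, i.e. the equilibrium transition matrix.
    """
    H = tridiagonal_hamiltonian(2, 0.0, 1.0, 0.0, 1.0)
    K = tridiagonal_generator(2, alpha, beta)
    builders = {
        "generator": lambda: coupling_from_generator(K),
        "transition": lambda: coupling_from_transition(K, tau),
        "scaled_transition": lambda: coupling_from_scaled_transition(K, tau),
    }
    return OpenSystemModel(H, builders[coupling_kind](), w)


def two_state_trajectory(
    alpha: float,
    beta: float,
    w: float,
    coupling_kind: str,
    t_grid: Sequence[float],
    tau: float = np.inf,
    rho0: Optional[DensityState] = None,
) -> np.ndarray:
    """p(down state) = rho_22(t) for the two-level open system.

    The default initial state is the up state |0><0| (evidence against),
    so the probability of the down ('yes') response rises toward its
    equilibrium: beta/(alpha+beta) for G=K, (1/3)(1+beta/(alpha+beta))
    for G=T at large tau -- strictly below the Markov asymptote.
    """
    model = two_state_model(alpha, beta, w, coupling_kind, tau)
    if rho0 is None:
        rho0 = DensityState(np.diag([1.0, 0.0]).astype(complex))
    traj = propagate_density_grid(
        model, rho0, t_grid, method="superop_expm", check_positivity=False
    )
    return np.array([r.diagonal[1] for r in traj])


@dataclass
class EvidenceTrajectories:
    """Mean-evidence curves and snapshots for the four lattice models."""

    t_grid: np.ndarray
    means: Dict[str, np.ndarray]
    snapshots: Dict[str, np.ndarray]
    markov_invariant_mean: float
    equilibrium_means: Dict[str, float]


def evidence_trajectory(
    n_levels: int = 101,
    alpha: float = 10.0,
    beta: float = 11.0,
    b: float = 16.0,
    sigma: float = 1.0,
    w: float = 0.5,
    t_grid: Optional[Sequence[float]] = None,
    tau: float = 1.0,
    center: Optional[int] = None,
    std: Optional[float] = None,
    snapshot_index: int = -1,
    compute_equilibria: bool = True,
) -> EvidenceTrajectories:
    """Run the four lattice models from a Gaussian / root-Gaussian start.

    Models: pure Markov (generator K), pure quantum (tridiagonal H with
    linear potential), open system with G=K, open system with G=T(tau),
    all at mixing weight ``w`` for the open systems.  Returns the
    mean-evidence series on ``t_grid``, the level distributions at the
    snapshot grid point, the Markov invariant mean, and (optionally) the
    open systems' stationary means computed by the equilibrium solver.

    Defaults reproduce the package's reference conditions: positive drift
    (beta > alpha) pushing the Markov walk right, a potential steep enough
    that the quantum packet oscillates in roughly [0.5, 0.75].
    """
    scale = EvidenceScale(n_levels)
    if t_grid is None:
        t_grid = np.linspace(0.0, 120.0, 121)[1:]
    t_grid = np.asarray(t_grid, dtype=float)
    if center is None:
        center = (n_levels - 1) // 2
    if std is None:
        std = n_levels / 10.0

    K = tridiagonal_generator(n_levels, alpha, beta)
    H = tridiagonal_hamiltonian(n_levels, 0.0, b, 0.0, sigma)
    phi0 = make_gaussian_probability(scale, center, std)
    psi0 = probability_to_amplitude(phi0)
    rho0 = pure_density(psi0)

    means: Dict[str, np.ndarray] = {}
    snapshots: Dict[str, np.ndarray] = {}

    # pure Markov
    dists = []
    vec = phi0.probs
    t_prev = 0.0
    for t in t_grid:
        vec = _markov_step(K, vec, t - t_prev)
        t_prev = t
        dists.append(vec.copy())
    means["markov"] = np.array(
        [mean_evidence(ProbabilityState(d), scale) for d in dists]
    )
    snapshots["markov"] = dists[snapshot_index]

    # pure quantum
    qdists = []
    for t in t_grid:
        u = unitary(H, t)
        qdists.append(np.abs(u @ psi0.amps) ** 2)
    means["quantum"] = np.array([float(scale.level_values @ d) for d in qdists])
    snapshots["quantum"] = qdists[snapshot_index]

    # open systems
    open_models = {
        "open_K": OpenSystemModel(H, coupling_from_generator(K), w),
        "open_T": OpenSystemModel(H, coupling_from_transition(K, tau), w),
    }
    equilibrium_means: Dict[str, float] = {}
    for name, model in open_models.items():
        traj = propagate_density_grid(model, rho0, t_grid, check_positivity=False)
        means[name] = np.array([mean_evidence(r, scale) for r in traj])
        snapshots[name] = traj[snapshot_index].diagonal
        if compute_equilibria:
            eq = equilibrium(model)
            equilibrium_means[name] = (
                mean_evidence(eq, scale) if eq is not None else float("nan")
            )

    return EvidenceTrajectories(
        t_grid=t_grid,
        means=means,
        snapshots=snapshots,
        markov_invariant_mean=mean_evidence(invariant_distribution(K), scale),
        equilibrium_means=equilibrium_means,
    )
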