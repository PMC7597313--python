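"""Quantum-Markov open-system dynamics (Lindblad master equation).

The unified accumulator evolves a density matrix under a weighted master
equation

    d rho/dt = -i (1-w) [H, rho]
               + w * sum_ij gamma_ij ( L_ij rho L_ij^dag
                                       - 1/2 {L_ij^dag L_ij, rho} ),

with elementary jump operators ``L_ij = |i><j|`` (move amplitude to level
i from level j) and coupling coefficients ``gamma_ij`` forming a matrix
``G``.  The weight ``w`` interpolates between the pure quantum walk
(w = 0) and a purely dissipative, Markov-like flow (w = 1).

For this operator basis the dissipator collapses to a closed form: with
``d = diag(rho)`` and column sums ``c_k = sum_i gamma_ik``,

    diagonal:      (G d)_k - c_k d_k          (a classical master equation)
    off-diagonal:  -1/2 (c_k + c_l) rho_kl    (coherence damping)

so the diagonal flow is exactly the Markov forward equation when G = K
(the Markov intensity matrix, column sums 0 -> no coherence damping), and
``d phi/dt = (T(tau) - I) phi`` when G = T(tau) (column sums 1 ->
coherences decay as exp(-w t)).  ``G = T(tau)/tau`` approximates K on the
diagonal while damping coherences at rate 1/tau.

Two independent solution routes are provided -- the vectorised
superoperator exponential and direct ODE integration of the right-hand
side -- and they are required to agree; the equilibrium solver extracts
the stationary density from the superoperator's null space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.linalg import expm, null_space
from scipy.sparse.linalg import expm_multiply, spsolve

from .markov_walk import MarkovGenerator, transition_matrix
from .quantum_walk import Hamiltonian
from .state_space import DensityState, ResponseProjector

__all__ = [
    "LindbladCoupling",
    "OpenSystemModel",
    "Superoperator",
    "PositivityWarning",
    "NumericalContractError",
    "coupling_from_generator",
    "coupling_from_transition",
    "coupling_from_scaled_transition",
    "off_diagonal_rate",
    "master_rhs",
    "build_superoperator",
    "propagate_density",
    "propagate_density_grid",
    "equilibrium",
    "joint_response_probability_open",
]

_PSD_TOL = 1e-10
_TRACE_TOL = 1e-8
# dense N^2 x N^2 exponential up to this lattice size; sparse action beyond
_DENSE_N_MAX = 32


class PositivityWarning(UserWarning):
    """A propagated density developed a negative eigenvalue.

    Only possible (and therefore only tolerated) when the coupling G is not
    completely positive, e.g. G = K."""


class NumericalContractError(RuntimeError):
    """A numerical invariant (trace, Hermiticity, method agreement) failed."""


@dataclass
class LindbladCoupling:
    """Coefficient matrix G of the dissipator, with its provenance tag.

    ``kind`` records how G was built: ``generator`` (G = K),
    ``transition`` (G = T(tau)), ``scaled_transition`` (G = T(tau)/tau) or
    ``custom``.  ``is_positive`` diagnoses whether the dissipator is a
    completely positive (density-preserving) flow: in the fixed jump basis
    L_ij = |i><j| the GKSL coefficient matrix is diagonal with entries
    gamma_ij, so complete positivity is exactly entrywise nonnegativity of
    G.  It is recorded, not enforced -- G = K deliberately violates it.
    """

    gamma: np.ndarray
    kind: str = "custom"
    tau: Optional[float] = None

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError(f"coupling must be square, got {g.shape}")
        if self.kind not in ("generator", "transition", "scaled_transition", "custom"):
            raise ValueError(f"unknown coupling kind {self.kind!r}")
        if self.kind == "generator":
            if np.abs(g.sum(axis=0)).max() > 1e-9:
                raise ValueError("generator coupling columns must sum to 0")
        elif self.kind == "transition":
            if np.any(g < -1e-10) or np.abs(g.sum(axis=0) - 1.0).max() > 1e-9:
                raise ValueError("transition coupling must be column-stochastic")
        self.gamma = g

    @property
    def n_levels(self) -> int:
        return self.gamma.shape[0]

    @property
    def column_sums(self) -> np.ndarray:
        """c_k = sum_i gamma_ik; the per-column coherence-decay rates at w=1."""
        return self.gamma.sum(axis=0)

    @property
    def is_positive(self) -> bool:
        """True when the dissipator is completely positive (all rates >= 0)."""
        return bool(self.gamma.min() >= -_PSD_TOL)


@dataclass
class OpenSystemModel:
    """(H, G, w) with the fixed convention L_ij = |i><j|."""

    hamiltonian: Hamiltonian
    coupling: LindbladCoupling
    w: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"weight w must lie in [0, 1], got {self.w}")
        if self.hamiltonian.n_levels != self.coupling.n_levels:
            raise ValueError("Hamiltonian and coupling dimensions differ")

    @property
    def n_levels(self) -> int:
        return self.hamiltonian.n_levels


@dataclass
class Superoperator:
    """N^2 x N^2 generator acting on column-stacked densities.

    ``vec(rho)`` stacks the columns of rho (Fortran order); the flow
    ``vec(rho(t)) = exp(t L) vec(rho(0))`` preserves the de-vectorised
    trace exactly.
    """

    matrix: Union[np.ndarray, sp.spmatrix]
    n_levels: int

    def apply(self, rho: np.ndarray) -> np.ndarray:
        """De-vectorised action L(rho) as an N x N matrix."""
        n = self.n_levels
        return np.asarray(self.matrix @ rho.reshape(-1, order="F")).reshape(
            (n, n), order="F"
        )


# ---------------------------------------------------------------------------
# coupling constructors

def coupling_from_generator(K: MarkovGenerator) -> LindbladCoupling:
    """G = K: the open system's diagonal flow is exactly the Markov walk.

    Column sums are zero, so coherences are untouched by the dissipator;
    the price is a dissipator that is not completely positive (K has
    negative diagonal rates), so positivity of rho is monitored rather
    than guaranteed.
    """
    return LindbladCoupling(K.matrix.copy(), kind="generator")


def coupling_from_transition(K: MarkovGenerator, tau: float) -> LindbladCoupling:
    """G = T(tau) = exp(K tau): a completely positive, column-stochastic coupling.

    ``tau = numpy.inf`` uses the equilibrium transition matrix (all columns
    equal to the stationary distribution), the limit used in the two-state
    closed-form example.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if np.isinf(tau):
        from .markov_walk import invariant_distribution

        phi = invariant_distribution(K).probs
        g = np.tile(phi[:, None], (1, K.n_levels))
    else:
        g = transition_matrix(K, tau).matrix
    return LindbladCoupling(g, kind="transition", tau=tau)


def coupling_from_scaled_transition(K: MarkovGenerator, tau: float) -> LindbladCoupling:
    """G = T(tau)/tau for small tau: approximates G=K on the diagonal flow
    (via (T(tau)-I)/tau -> K) while keeping all rates nonnegative; the cost
    is coherence damping at the fast rate 1/tau."""
    if not 0 < tau <= 1:
        raise ValueError("tau must lie in (0, 1]")
    g = transition_matrix(K, tau).matrix / tau
    return LindbladCoupling(g, kind="scaled_transition", tau=tau)


def off_diagonal_rate(G: LindbladCoupling) -> np.ndarray:
    """Per-column coherence decay rates c_k = sum_i gamma_ik.

    At w=1 the coherence rho_kl decays at rate (c_k + c_l)/2: 0 for G=K,
    1 for G=T(tau), 1/tau for G=T(tau)/tau.
    """
    return G.column_sums


# ---------------------------------------------------------------------------
# the master equation

def master_rhs(model: OpenSystemModel, rho: np.ndarray) -> np.ndarray:
    """Right-hand side of the master equation, evaluated in closed form.

    Uses the |i><j| reduction (see module docstring) instead of summing
    N^2 operator sandwiches, so one evaluation is O(N^2).  The output is
    traceless to machine precision, which is what keeps Tr rho = 1 along
    the flow.
    """
    rho = np.asarray(rho, dtype=complex)
    n = model.n_levels
    if rho.shape != (n, n):
        raise ValueError(f"expected {(n, n)} matrix, got {rho.shape}")
    h = model.hamiltonian.matrix
    g = model.coupling.gamma
    c = model.coupling.column_sums
    out = np.zeros_like(rho)
    if model.w < 1.0:
        out += -1j * (1.0 - model.w) * (h @ rho - rho @ h)
    if model.w > 0.0:
        d = np.real(np.diag(rho))
        diss = -0.5 * (c[:, None] + c[None, :]) * rho
        diss[np.diag_indices(n)] += g @ d
        out += model.w * diss
    return out


def build_superoperator(model: OpenSystemModel, sparse: bool = False) -> Superoperator:
    """Assemble the N^2 x N^2 generator on column-stacked densities.

    Hamiltonian part: -i(1-w)(I kron H - H^T kron I).  Dissipator part,
    via L_ij* kron L_ij = E_ij kron E_ij: a coupling between the diagonal
    vec-slots with coefficients gamma_ij, plus the diagonal damping
    -1/2 (c_a + c_b) at vec slot (a, b).  Must agree with
    :func:`master_rhs` applied to any density (tested against it).
    """
    n = model.n_levels
    h = model.hamiltonian.matrix
    g = model.coupling.gamma
    c = model.coupling.column_sums
    eye = sp.identity(n, format="csr")
    L = sp.csr_matrix((n * n, n * n), dtype=complex)
    if model.w < 1.0:
        hs = sp.csr_matrix(h)
        L = L + (-1j * (1.0 - model.w)) * (
            sp.kron(eye, hs, format="csr") - sp.kron(hs.T, eye, format="csr")
        )
    if model.w > 0.0:
        # sum_ij gamma_ij E_ij kron E_ij: entry (i*n+i, j*n+j) = gamma_ij
        diag_slots = np.arange(n) * n + np.arange(n)
        rows = np.repeat(diag_slots, n)
        cols = np.tile(diag_slots, n)
        vals = g.flatten()  # gamma[i, j] at (slot_i, slot_j), row-major
        jump = sp.csr_matrix((vals, (rows, cols)), shape=(n * n, n * n))
        damp = sp.diags(-0.5 * (np.add.outer(c, c)).flatten(order="F"))
        L = L + model.w * (jump + damp)
    if not sparse:
        return Superoperator(np.asarray(L.todense()), n)
    return Superoperator(L.tocsr(), n)


def _finalize_density(
    mat: np.ndarray, model: OpenSystemModel, check_positivity: bool
) -> DensityState:
    tr = np.trace(mat)
    if abs(tr - 1.0) > _TRACE_TOL:
        raise NumericalContractError(f"trace drift: Tr rho = {tr!r}")
    herm = np.max(np.abs(mat - mat.conj().T))
    if herm > _TRACE_TOL:
        raise NumericalContractError(f"Hermiticity drift {herm:.3e}")
    mat = (mat + mat.conj().T) / 2.0
    allow = not model.coupling.is_positive
    if check_positivity:
        lam_min = float(np.linalg.eigvalsh(mat)[0])
        if lam_min < -1e-8:
            if not allow:
                raise NumericalContractError(
                    f"negative eigenvalue {lam_min:.3e} under a completely "
                    "positive coupling (integration bug)"
                )
            warnings.warn(
                f"density eigenvalue {lam_min:.3e} < 0 under non-CP coupling "
                f"G={model.coupling.kind}",
                PositivityWarning,
                stacklevel=3,
            )
    return DensityState(mat, allow_nonpositive=allow)


def propagate_density(
    model: OpenSystemModel,
    rho0: DensityState,
    t: float,
    method: str = "auto",
    check_positivity: bool = True,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> DensityState:
    """Evolve rho0 for time t under the master equation.

    ``method``:

    * ``superop_expm`` -- dense matrix exponential of t*L (exact up to
      expm accuracy; default for N <= 32);
    * ``expm_multiply`` -- sparse exponential action (default above);
    * ``ode`` -- adaptive DOP853 integration of :func:`master_rhs`, an
      independent route used to cross-validate the superoperator.

    Trace and Hermiticity are enforced to 1e-8; positivity is checked and
    a violation is an error under a completely positive coupling but only
    a :class:`PositivityWarning` under e.g. G = K.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    n = model.n_levels
    if rho0.n_levels != n:
        raise ValueError("state and model dimensions differ")
    if method == "auto":
        method = "superop_expm" if n <= _DENSE_N_MAX else "expm_multiply"
    v0 = rho0.matrix.reshape(-1, order="F")
    if method == "superop_expm":
        L = build_superoperator(model, sparse=False)
        v = expm(L.matrix * t) @ v0
    elif method == "expm_multiply":
        L = build_superoperator(model, sparse=True)
        v = expm_multiply(L.matrix * t, v0)
    elif method == "ode":
        sol = solve_ivp(
            lambda _t, y: master_rhs(model, y.reshape((n, n), order="F")).reshape(
                -1, order="F"
            ),
            (0.0, t),
            v0.astype(complex),
            method="DOP853",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise NumericalContractError(f"ODE integration failed: {sol.message}")
        v = sol.y[:, -1]
    else:
        raise ValueError(f"unknown method {method!r}")
    return _finalize_density(
        v.reshape((n, n), order="F"), model, check_positivity
    )


def propagate_density_grid(
    model: OpenSystemModel,
    rho0: DensityState,
    t_grid: Sequence[float],
    method: str = "auto",
    check_positivity: bool = True,
) -> list:
    """Evolve along an increasing time grid, reusing work between points."""
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValueError("time grid must be strictly increasing and nonnegative")
    n = model.n_levels
    if method == "auto":
        method = "superop_expm" if n <= _DENSE_N_MAX else "expm_multiply"
    out = []
    if method == "superop_expm":
        L = build_superoperator(model, sparse=False).matrix
        v = rho0.matrix.reshape(-1, order="F")
        t_prev = 0.0
        for t in t_grid:
            v = expm(L * (t - t_prev)) @ v
            t_prev = t
            out.append(
                _finalize_density(
                    v.reshape((n, n), order="F"), model, check_positivity
                )
            )
    elif method == "expm_multiply":
        Lsp = build_superoperator(model, sparse=True).matrix
        v = rho0.matrix.reshape(-1, order="F").astype(complex)
        t_prev = 0.0
        for t in t_grid:
            if t > t_prev:
                v = expm_multiply(Lsp * (t - t_prev), v)
            t_prev = t
            out.append(
                _finalize_density(
                    v.reshape((n, n), order="F"), model, check_positivity
                )
            )
    else:
        for t in t_grid:
            out.append(
                propagate_density(
                    model, rho0, t, method=method, check_positivity=check_positivity
                )
            )
    return out


# ---------------------------------------------------------------------------
# equilibrium

def equilibrium(
    model: OpenSystemModel, check_positivity: bool = False
) -> Optional[DensityState]:
    """Stationary density: L vec(rho*) = 0, Hermitian, trace 1.

    Small systems use a dense SVD null space (so degeneracy -- a
    stationary set of dimension > 1 -- is detected exactly and reported
    with a warning, returning None).  Large systems solve the singular
    linear system directly with the trace condition replacing one row,
    then verify the residual.
    """
    n = model.n_levels
    if n <= _DENSE_N_MAX:
        L = build_superoperator(model, sparse=False).matrix
        ns = null_space(L, rcond=1e-10)
        dim = ns.shape[1]
        if dim != 1:
            warnings.warn(
                f"stationary set has dimension {dim}; no unique equilibrium",
                UserWarning,
                stacklevel=2,
            )
            return None
        rho = ns[:, 0].reshape((n, n), order="F")
    else:
        Lsp = build_superoperator(model, sparse=True).matrix.tolil()
        # replace the first row with the trace functional, RHS e_0
        trace_row = np.zeros(n * n, dtype=complex)
        trace_row[np.arange(n) * n + np.arange(n)] = 1.0
        Lsp[0, :] = trace_row
        b = np.zeros(n * n, dtype=complex)
        b[0] = 1.0
        v = spsolve(Lsp.tocsc(), b)
        rho = v.reshape((n, n), order="F")
        resid = build_superoperator(model, sparse=True).apply(rho)
        if np.max(np.abs(resid)) > 1e-6 * max(1.0, np.abs(rho).max()):
            warnings.warn(
                "large residual in stationary solve; stationary set may be "
                "degenerate",
                UserWarning,
                stacklevel=2,
            )
            return None
    rho = (rho + rho.conj().T) / 2.0
    tr = np.trace(rho).real
    if abs(tr) < 1e-12:
        warnings.warn("stationary null vector is traceless", UserWarning, stacklevel=2)
        return None
    rho = rho / tr
    lam_min = float(np.linalg.eigvalsh(rho)[0])
    if check_positivity and lam_min < -1e-8 and model.coupling.is_positive:
        raise NumericalContractError(
            f"equilibrium eigenvalue {lam_min:.3e} < 0 under a CP coupling"
        )
    return DensityState(rho, allow_nonpositive=lam_min < -1e-8 or not model.coupling.is_positive)


# ---------------------------------------------------------------------------
# sequential measurement

def joint_response_probability_open(
    model: OpenSystemModel,
    rho0: DensityState,
    schedule: Sequence[Tuple[ResponseProjector, float]],
    method: str = "auto",
) -> float:
    """Probability of an ordered response sequence under open dynamics.

    Alternates master-equation propagation over each interval with
    unnormalised Lueders projections; the joint probability is the trace
    of the final branch matrix.  Reduces to the quantum rule at w=0 and,
    with G=K, to the Markov rule on the diagonal at w=1.
    """
    times = [t for _, t in schedule]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])) or (times and times[0] < 0):
        raise ValueError("measurement times must be strictly increasing and >= 0")
    n = model.n_levels
    if method == "auto":
        method = "superop_expm" if n <= _DENSE_N_MAX else "expm_multiply"
    if method == "superop_expm":
        L = build_superoperator(model, sparse=False).matrix
        step = lambda v, dt: expm(L * dt) @ v  # noqa: E731
    elif method == "expm_multiply":
        Lsp = build_superoperator(model, sparse=True).matrix
        step = lambda v, dt: expm_multiply(Lsp * dt, v)  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")
    v = rho0.matrix.reshape(-1, order="F").astype(complex)
    t_prev = 0.0
    for M, t in schedule:
        if M.n_levels != n:
            raise ValueError("projector dimension mismatch")
        if t > t_prev:
            v = step(v, t - t_prev)
        mat = M.sandwich(v.reshape((n, n), order="F"))
        v = mat.reshape(-1, order="F")
        t_prev = t
    return float(np.trace(v.reshape((n, n), order="F")).real)
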