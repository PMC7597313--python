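"""Pure quantum walk on the evidence lattice.

Amplitudes evolve under the Schroedinger equation ``d psi/dt = -i H psi``
with a Hermitian Hamiltonian ``H``, solved by the unitary
``U(t) = exp(-i H t)``.  The lattice Hamiltonian is tridiagonal: constant
off-diagonal coupling ``sigma`` (the hopping that spreads amplitude) and a
diagonal potential ``mu(x) = a + b x + c x^2`` evaluated at the level
values ``x = j/(N-1)`` (a positive slope ``b`` pushes the packet toward
high evidence, where the reflecting bound bounces it back -- the source of
the characteristic preference/confidence oscillations).

Measurement uses the L2 rule ``p(R) = ||M psi||^2`` (equivalently the
trace rule on densities), and a recorded response collapses the state by
the Lueders projection ``rho -> M rho M / p``.  Because collapse is not a
simple restriction of probabilities, sequential measurements interfere:
marginalising over an unrecorded intermediate outcome does *not* return
the unmeasured distribution (Chapman-Kolmogorov is violated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .state_space import AmplitudeState, DensityState, ResponseProjector

__all__ = [
    "Hamiltonian",
    "tridiagonal_hamiltonian",
    "unitary",
    "propagate_amplitude",
    "propagate_density_unitary",
    "response_probability_density",
    "collapse",
    "joint_response_probability_quantum",
]

_HERM_TOL = 1e-12


@dataclass
class Hamiltonian:
    """Hermitian generator of the quantum walk.

    The eigendecomposition is computed lazily and cached, so evaluating
    ``U(t)`` on many grid times costs one diagonalisation.
    """

    matrix: np.ndarray
    potential_params: Optional[Tuple[float, float, float]] = None
    sigma: Optional[float] = None
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        h = np.asarray(self.matrix, dtype=complex)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ValueError(f"Hamiltonian must be square, got {h.shape}")
        dev = np.max(np.abs(h - h.conj().T))
        if dev > max(_HERM_TOL, _HERM_TOL * np.abs(h).max()):
            raise ValueError(f"Hamiltonian must be Hermitian (deviation {dev:.3e})")
        self.matrix = h

    @property
    def n_levels(self) -> int:
        return self.matrix.shape[0]

    def eigensystem(self):
        if self._eig is None:
            lam, v = np.linalg.eigh(self.matrix)
            object.__setattr__(self, "_eig", (lam, v))
        return self._eig


def tridiagonal_hamiltonian(
    n_levels: int, a: float, b: float, c: float, sigma: float
) -> Hamiltonian:
    """Lattice Hamiltonian: diagonal quadratic potential, off-diagonal sigma.

    ``mu(x_j) = a + b x_j + c x_j^2`` with ``x_j = j/(N-1)``.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    x = np.arange(n_levels) / (n_levels - 1)
    h = np.diag(a + b * x + c * x**2).astype(complex)
    idx = np.arange(n_levels - 1)
    h[idx + 1, idx] = sigma
    h[idx, idx + 1] = sigma
    return Hamiltonian(h, potential_params=(a, b, c), sigma=sigma)


def unitary(H: Hamiltonian, t: float) -> np.ndarray:
    """U(t) = exp(-i H t) via the cached Hermitian eigendecomposition."""
    lam, v = H.eigensystem()
    return (v * np.exp(-1j * lam * t)) @ v.conj().T


def propagate_amplitude(H: Hamiltonian, psi0: AmplitudeState, t: float) -> AmplitudeState:
    """psi(t) = U(t) psi(0); the L2 norm is preserved exactly."""
    if psi0.n_levels != H.n_levels:
        raise ValueError("state and Hamiltonian dimensions differ")
    return AmplitudeState(unitary(H, t) @ psi0.amps)


def propagate_density_unitary(H: Hamiltonian, rho0: DensityState, t: float) -> DensityState:
    """rho(t) = U(t) rho(0) U(t)^dagger (spectrum-preserving conjugation)."""
    if rho0.n_levels != H.n_levels:
        raise ValueError("state and Hamiltonian dimensions differ")
    u = unitary(H, t)
    return DensityState(
        u @ rho0.matrix @ u.conj().T, allow_nonpositive=rho0.allow_nonpositive
    )


def response_probability_density(M: ResponseProjector, rho: DensityState) -> float:
    """Trace rule: p(R) = Tr(M rho M) = sum of rho's diagonal over M's levels."""
    if M.n_levels != rho.n_levels:
        raise ValueError("projector and state dimensions differ")
    return float(rho.diagonal[list(M.levels)].sum())


def collapse(M: ResponseProjector, rho: DensityState) -> Tuple[DensityState, float]:
    """Lueders projection: renormalised post-state M rho M / p, and p.

    Raises on a zero-probability outcome.  The unnormalised branch matrix
    (what joint sequential probabilities chain together) is available as
    ``M.sandwich(rho.matrix)``.
    """
    post = M.sandwich(rho.matrix)
    prob = float(np.trace(post).real)
    if prob <= 0:
        raise ValueError(f"cannot condition on zero-probability outcome {M.label!r}")
    return (
        DensityState(post / prob, allow_nonpositive=rho.allow_nonpositive),
        prob,
    )


def joint_response_probability_quantum(
    H: Hamiltonian,
    state0: Union[AmplitudeState, DensityState],
    schedule: Sequence[Tuple[ResponseProjector, float]],
) -> float:
    """Probability of an ordered response sequence under unitary dynamics.

    Alternates unitary propagation with unnormalised Lueders projection;
    the result is the trace of the final branch matrix (density input) or
    the squared norm of the final branch vector (amplitude input).  The
    two forms agree for pure initial states.
    """
    times = [t for _, t in schedule]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])) or (times and times[0] < 0):
        raise ValueError("measurement times must be strictly increasing and >= 0")
    t_prev = 0.0
    if isinstance(state0, AmplitudeState):
        vec = state0.amps.copy()
        for M, t in schedule:
            vec = unitary(H, t - t_prev) @ vec
            vec = M.apply_vector(vec)
            t_prev = t
        return float(np.sum(np.abs(vec) ** 2))
    mat = state0.matrix.copy()
    for M, t in schedule:
        u = unitary(H, t - t_prev)
        mat = M.sandwich(u @ mat @ u.conj().T)
        t_prev = t
    return float(np.trace(mat).real)
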