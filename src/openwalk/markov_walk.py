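"""Continuous-time Markov random walk on the evidence lattice.

The classical accumulator: a birth-death chain with upward rate ``beta``
(toward high evidence) and downward rate ``alpha``, reflecting bounds at
both ends.  The belief vector obeys the Kolmogorov forward equation
``d phi/dt = K phi`` with intensity matrix ``K`` (nonnegative off-diagonal,
columns summing to zero), solved by the transition matrix
``T(t) = exp(K t)``.  Measurement follows the L1 rule: the probability of
a response is the summed probability over its projector's levels, and a
recorded response simply restricts the vector to those levels (no
interference), which is why sequential response probabilities satisfy the
Chapman-Kolmogorov equation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm, null_space

from .state_space import ProbabilityState, ResponseProjector

__all__ = [
    "MarkovGenerator",
    "TransitionMatrix",
    "tridiagonal_generator",
    "approximate_generator",
    "transition_matrix",
    "propagate",
    "response_probability",
    "joint_response_probability",
    "invariant_distribution",
]

_COLSUM_TOL = 1e-12


@dataclass
class MarkovGenerator:
    """Intensity matrix K: nonnegative off-diagonal, columns sum to zero.

    ``alpha``/``beta`` are recorded when the generator is built as a
    tridiagonal birth-death chain; ``drift`` and ``diffusion`` are the
    standard random-walk moments (beta-alpha)/2 and (beta+alpha)/2.
    """

    matrix: np.ndarray
    alpha: Optional[float] = None
    beta: Optional[float] = None

    def __post_init__(self) -> None:
        k = np.asarray(self.matrix, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError(f"generator must be square, got {k.shape}")
        off = k - np.diag(np.diag(k))
        if np.any(off < -_COLSUM_TOL):
            raise ValueError("generator off-diagonal entries must be nonnegative")
        colsum = np.abs(k.sum(axis=0)).max()
        if colsum > max(_COLSUM_TOL, 1e-12 * np.abs(k).max() * k.shape[0]):
            raise ValueError(f"generator columns must sum to 0 (max dev {colsum:.3e})")
        self.matrix = k

    @property
    def n_levels(self) -> int:
        return self.matrix.shape[0]

    @property
    def drift(self) -> float:
        """Mean drift rate mu = (beta - alpha)/2; positive pushes right."""
        if self.alpha is None or self.beta is None:
            raise ValueError("drift defined only for tridiagonal-rate generators")
        return (self.beta - self.alpha) / 2.0

    @property
    def diffusion(self) -> float:
        """Diffusion rate sigma^2 = (beta + alpha)/2."""
        if self.alpha is None or self.beta is None:
            raise ValueError("diffusion defined only for tridiagonal-rate generators")
        return (self.beta + self.alpha) / 2.0


@dataclass
class TransitionMatrix:
    """Column-stochastic T(t) = exp(K t) for a given horizon t."""

    matrix: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        t = np.asarray(self.matrix, dtype=float)
        if np.any(t < -1e-10) or np.any(t > 1.0 + 1e-10):
            raise ValueError("transition probabilities must lie in [0, 1]")
        colsum = np.abs(t.sum(axis=0) - 1.0).max()
        if colsum > 1e-10:
            raise ValueError(f"transition columns must sum to 1 (max dev {colsum:.3e})")
        self.matrix = np.clip(t, 0.0, 1.0)


def tridiagonal_generator(n_levels: int, alpha: float, beta: float) -> MarkovGenerator:
    """Birth-death generator with reflecting bounds.

    Sub-diagonal ``beta`` (up-moves toward high evidence), super-diagonal
    ``alpha`` (down-moves), interior diagonal ``-(alpha+beta)``; the corner
    diagonals are ``-beta`` and ``-alpha`` so no probability leaks at the
    bounds.  Irreducible (hence uniquely ergodic) whenever both rates are
    positive.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    if alpha < 0 or beta < 0:
        raise ValueError("rates must be nonnegative")
    if alpha + beta == 0:
        raise ValueError("at least one rate must be positive")
    k = np.zeros((n_levels, n_levels))
    idx = np.arange(n_levels - 1)
    k[idx + 1, idx] = beta
    k[idx, idx + 1] = alpha
    k -= np.diag(k.sum(axis=0))
    return MarkovGenerator(k, alpha=alpha, beta=beta)


def approximate_generator(K: MarkovGenerator, tau: float) -> MarkovGenerator:
    """Finite-difference generator (T(tau) - I)/tau.

    For small tau this approximates K; it is itself a valid intensity
    matrix for any tau > 0, and generates the same family of distributions
    as the Lindblad component with coupling G = T(tau) up to the time
    rescaling t -> t/tau.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = transition_matrix(K, tau).matrix
    return MarkovGenerator((t - np.eye(K.n_levels)) / tau)


def transition_matrix(K: MarkovGenerator, t: float) -> TransitionMatrix:
    """T(t) = exp(K t); column-stochastic, semigroup in t."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    return TransitionMatrix(expm(K.matrix * t), horizon=t)


def propagate(K: MarkovGenerator, phi0: ProbabilityState, t: float) -> ProbabilityState:
    """phi(t) = exp(K t) phi(0)."""
    if phi0.n_levels != K.n_levels:
        raise ValueError("state and generator dimensions differ")
    return ProbabilityState(transition_matrix(K, t).matrix @ phi0.probs)


def response_probability(M: ResponseProjector, phi: ProbabilityState) -> float:
    """L1 measurement rule: p(R) = ||M phi||_1 = sum of phi over M's levels."""
    if M.n_levels != phi.n_levels:
        raise ValueError("projector and state dimensions differ")
    return float(phi.probs[list(M.levels)].sum())


def joint_response_probability(
    K: MarkovGenerator,
    phi0: ProbabilityState,
    schedule: Sequence[Tuple[ResponseProjector, float]],
    return_conditional: bool = False,
):
    """Probability of an ordered sequence of responses at increasing times.

    Alternates propagation over each inter-measurement interval with
    restriction to the projector's levels (no renormalisation between
    measurements; the final L1 norm is the joint probability).  With
    ``return_conditional=True`` the renormalised post-final-measurement
    distribution is returned alongside the probability.
    """
    times = [t for _, t in schedule]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])) or (times and times[0] < 0):
        raise ValueError("measurement times must be strictly increasing and >= 0")
    vec = phi0.probs.copy()
    t_prev = 0.0
    for M, t in schedule:
        if M.n_levels != K.n_levels:
            raise ValueError("projector dimension mismatch")
        vec = expm(K.matrix * (t - t_prev)) @ vec
        vec = M.apply_vector(vec)
        t_prev = t
    prob = float(vec.sum())
    if return_conditional:
        cond = ProbabilityState(vec / prob) if prob > 0 else None
        return prob, cond
    return prob


def invariant_distribution(K: MarkovGenerator) -> ProbabilityState:
    """Unique stationary distribution phi* with K phi* = 0.

    Requires an irreducible generator (one-dimensional null space); a
    tridiagonal generator with both rates positive qualifies, and its
    stationary law is the detailed-balance geometric profile
    ``phi*_j proportional to (beta/alpha)^j``.
    """
    ns = null_space(K.matrix)
    if ns.shape[1] != 1:
        raise ValueError(
            f"stationary set is {ns.shape[1]}-dimensional; generator not irreducible"
        )
    v = ns[:, 0]
    v = v * np.sign(v.sum())
    return ProbabilityState(np.clip(v, 0.0, None) / np.clip(v, 0.0, None).sum())
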