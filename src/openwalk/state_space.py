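"""Evidence lattice, state representations, projectors, and summary functionals.

All models in this package live on a discrete *evidence lattice*: ``N``
ordered levels ``0 .. N-1``, level ``j`` standing for a likelihood
``j/(N-1)`` that the focal hypothesis (e.g. "signal present") is true.
Three state representations share this lattice:

* :class:`ProbabilityState` -- a classical probability vector ``phi``
  (epistemic uncertainty about where the evidence sits);
* :class:`AmplitudeState` -- a complex amplitude vector ``psi`` whose
  squared magnitudes are probabilities (ontic, superposed uncertainty);
* :class:`DensityState` -- a density matrix ``rho`` that encompasses both:
  classical mixtures of pure quantum states.

Responses (a binary choice, a confidence rating) are diagonal 0/1
projectors over subsets of levels (:class:`ResponseProjector`).

Level indexing is 0-based throughout.  Narrative descriptions of this kind
of model sometimes count matrix rows from 1 (level 65 living in "row 66");
here level ``j`` is always row index ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "PROB_TOL",
    "DENSITY_TOL",
    "EIG_TOL",
    "EvidenceScale",
    "ProbabilityState",
    "AmplitudeState",
    "DensityState",
    "ResponseProjector",
    "make_gaussian_probability",
    "probability_to_amplitude",
    "pure_density",
    "mixture_density",
    "projector_for_levels",
    "mean_evidence",
]

# Validation tolerances (package-wide constants; loaders may override the
# checks but these defaults are what every constructor enforces).
PROB_TOL = 1e-12    # L1 / L2 normalisation of phi and psi
DENSITY_TOL = 1e-10  # Hermiticity and trace of rho
EIG_TOL = 1e-8      # how negative an eigenvalue of rho may be


@dataclass(frozen=True)
class EvidenceScale:
    """The N-level evidence basis.

    Level ``j`` (0-based) carries the likelihood value ``j/(N-1)``, so the
    lattice spans [0, 1]: level 0 means the focal hypothesis is certainly
    false, level ``N-1`` certainly true, the midpoint equivocal.
    """

    n_levels: int

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"need at least 2 evidence levels, got {self.n_levels}")

    @property
    def level_values(self) -> np.ndarray:
        """Likelihood value of each level: ``j/(N-1)``, increasing 0 -> 1."""
        return np.arange(self.n_levels) / (self.n_levels - 1)


def _as_vector(x: Union[np.ndarray, Sequence], n: int | None = None) -> np.ndarray:
    v = np.asarray(x)
    if v.ndim != 1:
        raise ValueError(f"expected a vector, got shape {v.shape}")
    if n is not None and v.shape[0] != n:
        raise ValueError(f"expected length {n}, got {v.shape[0]}")
    return v


@dataclass
class ProbabilityState:
    """Classical belief state: probability ``probs[j]`` of evidence level j."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = _as_vector(self.probs).astype(float)
        if np.any(p < -PROB_TOL):
            raise ValueError("probabilities must be nonnegative")
        s = p.sum()
        if abs(s - 1.0) > max(PROB_TOL, PROB_TOL * p.size):
            raise ValueError(f"probabilities must sum to 1, got {s!r}")
        self.probs = np.clip(p, 0.0, None)

    @property
    def n_levels(self) -> int:
        return self.probs.shape[0]


@dataclass
class AmplitudeState:
    """Quantum belief state: complex amplitude ``amps[j]`` for level j."""

    amps: np.ndarray

    def __post_init__(self) -> None:
        a = _as_vector(self.amps).astype(complex)
        nrm = float(np.sum(np.abs(a) ** 2))
        if abs(nrm - 1.0) > max(PROB_TOL, PROB_TOL * a.size):
            raise ValueError(f"squared magnitudes must sum to 1, got {nrm!r}")
        self.amps = a

    @property
    def n_levels(self) -> int:
        return self.amps.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        """Born-rule probabilities |psi_j|^2."""
        return np.abs(self.amps) ** 2


@dataclass
class DensityState:
    """Density matrix state: Hermitian, trace one, positive semidefinite.

    ``allow_nonpositive=True`` skips the eigenvalue floor check.  The
    open-system dynamics with the non-completely-positive coupling G=K can
    push eigenvalues slightly negative; such states are representable but
    are flagged rather than silently accepted (see :mod:`openwalk.open_system`).
    """

    matrix: np.ndarray
    allow_nonpositive: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"density must be square, got shape {m.shape}")
        herm = np.max(np.abs(m - m.conj().T))
        if herm > DENSITY_TOL:
            raise ValueError(f"density not Hermitian (deviation {herm:.3e})")
        tr = np.trace(m)
        if abs(tr - 1.0) > DENSITY_TOL:
            raise ValueError(f"density trace must be 1, got {tr!r}")
        if not self.allow_nonpositive:
            lam = np.linalg.eigvalsh((m + m.conj().T) / 2.0)
            if lam[0] < -EIG_TOL:
                raise ValueError(
                    f"density has negative eigenvalue {lam[0]:.3e}; pass "
                    "allow_nonpositive=True to represent a non-physical state"
                )
        self.matrix = m

    @property
    def n_levels(self) -> int:
        return self.matrix.shape[0]

    @property
    def diagonal(self) -> np.ndarray:
        """Real diagonal: the probabilities of observing each level."""
        return self.matrix.diagonal().real.copy()

    def min_eigenvalue(self) -> float:
        """Smallest eigenvalue (negative values signal a non-physical state)."""
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def coherence_l1(self) -> float:
        """Sum of absolute off-diagonal magnitudes, a coherence measure."""
        m = np.abs(self.matrix)
        return float(m.sum() - np.trace(m).real)


@dataclass
class ResponseProjector:
    """Diagonal 0/1 measurement operator M_R over a subset of levels.

    A response R (a choice or a confidence rating) is identified with the
    set of lattice levels that express it; its projector has ones exactly
    at those levels.  Projectors for disjoint level sets are orthogonal,
    and a family of projectors whose level sets partition the lattice sums
    to the identity (a complete measurement).
    """

    levels: tuple
    n_levels: int
    label: str = ""

    def __post_init__(self) -> None:
        levels = tuple(sorted(set(int(j) for j in self.levels)))
        if not levels:
            raise ValueError("projector needs at least one level")
        if levels[0] < 0 or levels[-1] >= self.n_levels:
            raise ValueError(f"levels {levels} out of range for N={self.n_levels}")
        self.levels = levels

    @property
    def matrix(self) -> np.ndarray:
        m = np.zeros((self.n_levels, self.n_levels))
        idx = np.array(self.levels)
        m[idx, idx] = 1.0
        return m

    @property
    def mask(self) -> np.ndarray:
        """Boolean selector over levels (True where the projector has a 1)."""
        mask = np.zeros(self.n_levels, dtype=bool)
        mask[list(self.levels)] = True
        return mask

    def apply_vector(self, vec: np.ndarray) -> np.ndarray:
        """M @ vec, without materialising the matrix."""
        out = np.zeros_like(np.asarray(vec))
        out[list(self.levels)] = np.asarray(vec)[list(self.levels)]
        return out

    def sandwich(self, rho: np.ndarray) -> np.ndarray:
        """M @ rho @ M (unnormalised Lueders post-measurement matrix)."""
        mask = self.mask
        out = np.zeros_like(np.asarray(rho, dtype=complex))
        out[np.ix_(mask, mask)] = np.asarray(rho)[np.ix_(mask, mask)]
        return out


# ---------------------------------------------------------------------------
# constructors

def make_gaussian_probability(
    scale: EvidenceScale, center: float, std: float
) -> ProbabilityState:
    """Discrete Gaussian belief profile on the lattice.

    Entries are proportional to ``exp(-(j-center)^2 / (2 std^2))``,
    truncated to the lattice (no wrap-around) and renormalised.  ``std``
    is in level units.  As ``std -> 0`` this tends to a point mass at the
    nearest level.
    """
    n = scale.n_levels
    if std <= 0:
        raise ValueError(f"std must be positive, got {std}")
    if not 0 <= center <= n - 1:
        raise ValueError(f"center {center} outside levels 0..{n - 1}")
    j = np.arange(n, dtype=float)
    z = -((j - center) ** 2) / (2.0 * std**2)
    p = np.exp(z - z.max())  # stable for tiny std
    return ProbabilityState(p / p.sum())


def probability_to_amplitude(p: ProbabilityState) -> AmplitudeState:
    """Real nonnegative amplitudes ``sqrt(p_j)``.

    The resulting pure quantum state reproduces ``p`` under any projective
    measurement in the evidence basis.
    """
    return AmplitudeState(np.sqrt(p.probs).astype(complex))


def pure_density(psi: AmplitudeState) -> DensityState:
    """Rank-one density ``psi psi^dagger`` of a pure state."""
    return DensityState(np.outer(psi.amps, psi.amps.conj()))


def mixture_density(
    weights: Sequence[float], states: Sequence[AmplitudeState]
) -> DensityState:
    """Classical mixture ``sum_j p_j psi_j psi_j^dagger`` of pure states."""
    w = np.asarray(weights, dtype=float)
    if len(states) != w.shape[0]:
        raise ValueError(f"{w.shape[0]} weights for {len(states)} states")
    if np.any(w < -PROB_TOL) or abs(w.sum() - 1.0) > max(PROB_TOL, PROB_TOL * w.size):
        raise ValueError("weights must be a probability simplex vector")
    n = states[0].n_levels
    rho = np.zeros((n, n), dtype=complex)
    for wk, psi in zip(w, states):
        if psi.n_levels != n:
            raise ValueError("all states must share one lattice dimension")
        rho += wk * np.outer(psi.amps, psi.amps.conj())
    return DensityState(rho)


def projector_for_levels(
    scale: EvidenceScale, levels: Iterable[int], label: str = ""
) -> ResponseProjector:
    """Projector with ones exactly at the given (0-based) levels."""
    return ResponseProjector(tuple(levels), scale.n_levels, label)


def mean_evidence(
    state: Union[ProbabilityState, DensityState], scale: EvidenceScale
) -> float:
    """Expected likelihood value ``sum_j (j/(N-1)) p_j`` in [0, 1].

    For a density the diagonal supplies the level probabilities.
    """
    if isinstance(state, ProbabilityState):
        p = state.probs
    elif isinstance(state, DensityState):
        p = state.diagonal
    else:
        raise TypeError(f"expected ProbabilityState or DensityState, got {type(state)}")
    if p.shape[0] != scale.n_levels:
        raise ValueError("state and scale dimensions differ")
    return float(np.dot(scale.level_values, p))
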