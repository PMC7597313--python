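"""Shared fixtures: random model instances and the literal-sum dissipator.

The literal oracle builds every jump operator L_ij = |i><j| explicitly and
sums the N^2 operator sandwiches of the master equation.  It is kept
deliberately naive and independent of the closed-form implementation in
``openwalk.open_system`` so the two can cross-validate each other.
"""

import numpy as np
import pytest
from hypothesis import settings

from openwalk.cli_io import random_instance

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from openwalk.open_system import OpenSystemModel


def literal_master_rhs(model: OpenSystemModel, rho: np.ndarray) -> np.ndarray:
    """Brute-force master equation right-hand side (O(N^4))."""
    n = model.n_levels
    h = model.hamiltonian.matrix
    g = model.coupling.gamma
    w = model.w
    out = -1j * (1.0 - w) * (h @ rho - rho @ h)
    for i in range(n):
        for j in range(n):
            L = np.zeros((n, n))
            L[i, j] = 1.0
            LdL = L.T @ L
            out += w * g[i, j] * (
                L @ rho @ L.T - 0.5 * (LdL @ rho + rho @ LdL)
            )
    return out


@pytest.fixture
def oracle_rhs():
    return literal_master_rhs


@pytest.fixture
def make_instance():
    """Factory for random small (H, K, G, rho) instances, seeded."""

    def _make(seed, n_max=6):
        return random_instance(n_max=n_max, seed=seed)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240990)
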