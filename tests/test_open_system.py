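"""Open-system master equation: couplings, superoperator, propagation,
coherence laws, and the two-state closed-form equilibria."""

import warnings

import numpy as np
import pytest

from openwalk.markov_walk import propagate, transition_matrix, tridiagonal_generator
from openwalk.open_system import (
    LindbladCoupling,
    OpenSystemModel,
    PositivityWarning,
    build_superoperator,
    coupling_from_generator,
    coupling_from_scaled_transition,
    coupling_from_transition,
    equilibrium,
    joint_response_probability_open,
    master_rhs,
    off_diagonal_rate,
    propagate_density,
    propagate_density_grid,
)
from openwalk.quantum_walk import (
    joint_response_probability_quantum,
    propagate_density_unitary,
    tridiagonal_hamiltonian,
)
from openwalk.markov_walk import joint_response_probability
from openwalk.state_space import (
    DensityState,
    EvidenceScale,
    ProbabilityState,
    projector_for_levels,
)


def two_state_equilibrium_K(alpha, beta):
    """Hand-derived stationary density for w=0.5, H=[[0,1],[1,1]], G=K."""
    lam = alpha + beta
    r21 = (beta - alpha) / lam
    return np.array([[alpha / lam, r21], [r21, beta / lam]], dtype=complex)


def two_state_equilibrium_T(alpha, beta):
    """Hand-derived stationary density for w=0.5, H=[[0,1],[1,1]], G=T(inf)."""
    lam = alpha + beta
    r21 = (1 + 1j) / 6 * (1 - 2 * alpha / lam)
    return np.array(
        [
            [(1 + alpha / lam) / 3, np.conj(r21)],
            [r21, (1 + beta / lam) / 3],
        ]
    )


class TestCouplings:
    def test_generator_coupling(self):
        K = tridiagonal_generator(2, 1.0, 2.0)
        G = coupling_from_generator(K)
        np.testing.assert_allclose(G.gamma, [[-2, 1], [2, -1]])
        np.testing.assert_allclose(off_diagonal_rate(G), [0.0, 0.0], atol=1e-14)
        assert not G.is_positive  # negative diagonal rates

    def test_transition_coupling_is_stochastic(self):
        K = tridiagonal_generator(4, 1.0, 2.0)
        G = coupling_from_transition(K, 0.8)
        np.testing.assert_allclose(G.gamma.sum(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(off_diagonal_rate(G), 1.0, atol=1e-12)
        assert G.is_positive

    def test_transition_coupling_infinite_tau(self):
        K = tridiagonal_generator(2, 1.0, 2.0)
        G = coupling_from_transition(K, np.inf)
        np.testing.assert_allclose(G.gamma, [[1 / 3, 1 / 3], [2 / 3, 2 / 3]], atol=1e-12)

    def test_scaled_transition_approximates_generator(self):
        K = tridiagonal_generator(5, 1.0, 2.0)
        tau = 1e-4
        G = coupling_from_scaled_transition(K, tau)
        eye = np.eye(5)
        np.testing.assert_allclose(G.gamma - eye / tau, K.matrix, atol=1e-3)
        np.testing.assert_allclose(off_diagonal_rate(G), 1 / tau, rtol=1e-3)

    def test_scaled_transition_at_tau_one_matches_transition(self):
        K = tridiagonal_generator(3, 0.7, 1.1)
        a = coupling_from_scaled_transition(K, 1.0)
        b = coupling_from_transition(K, 1.0)
        np.testing.assert_allclose(a.gamma, b.gamma)

    @pytest.mark.parametrize("tau", [0.0, -0.5])
    def test_invalid_tau_rejected(self, tau):
        K = tridiagonal_generator(3, 1.0, 1.0)
        with pytest.raises(ValueError):
            coupling_from_transition(K, tau)
        with pytest.raises(ValueError):
            coupling_from_scaled_transition(K, tau)

    def test_kind_invariants_enforced(self):
        with pytest.raises(ValueError):
            LindbladCoupling(np.eye(2), kind="generator")  # columns sum to 1, not 0
        with pytest.raises(ValueError):
            LindbladCoupling(np.array([[0.5, 0.5], [0.4, 0.5]]), kind="transition")


class TestMasterRhs:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_literal_jump_operator_sum(self, seed, make_instance, oracle_rhs):
        """The O(N^2) closed-form dissipator agrees with the brute-force
        sum over all N^2 jump operators."""
        H, K, G, rho = make_instance(seed)
        w = [0.0, 0.25, 0.5, 0.75, 1.0][seed % 5]
        model = OpenSystemModel(H, G, w)
        got = master_rhs(model, rho.matrix)
        np.testing.assert_allclose(got, oracle_rhs(model, rho.matrix), atol=1e-12)
        assert abs(np.trace(got)) < 1e-12

    def test_pure_quantum_limit_is_commutator(self, make_instance):
        H, K, G, rho = make_instance(7)
        model = OpenSystemModel(H, G, 0.0)
        h = H.matrix
        np.testing.assert_allclose(
            master_rhs(model, rho.matrix),
            -1j * (h @ rho.matrix - rho.matrix @ h),
            atol=1e-13,
        )

    def test_dissipative_diagonal_is_classical_master_equation(self, make_instance):
        H, K, G, rho = make_instance(11)
        tau = 0.7
        G = coupling_from_transition(K, tau)
        model = OpenSystemModel(H, G, 1.0)
        out = master_rhs(model, rho.matrix)
        T = transition_matrix(K, tau).matrix
        expected_diag = (T - np.eye(K.n_levels)) @ rho.diagonal
        np.testing.assert_allclose(np.diag(out).real, expected_diag, atol=1e-12)

    def test_dissipative_offdiagonal_decay_rate(self, make_instance):
        H, K, G, rho = make_instance(13)
        G = coupling_from_transition(K, 0.9)
        model = OpenSystemModel(H, G, 1.0)
        out = master_rhs(model, rho.matrix)
        n = K.n_levels
        for k in range(n):
            for l in range(n):
                if k != l:
                    assert out[k, l] == pytest.approx(-rho.matrix[k, l], abs=1e-12)

    def test_two_state_explicit_form(self):
        """w=0.5, H=[[0,1],[1,1]], G=K: the right-hand side doubled equals
        -i[H,rho] + diag(alpha rho22 - beta rho11, beta rho11 - alpha rho22),
        whose off-diagonal reads -i(2 rho11 - 1 + rho21) on the lower entry
        for Hermitian trace-one rho."""
        alpha, beta = 1.0, 2.0
        rg = np.random.default_rng(5)
        B = rg.normal(size=(2, 2)) + 1j * rg.normal(size=(2, 2))
        m = B @ B.conj().T
        rho = m / np.trace(m).real
        H = tridiagonal_hamiltonian(2, 0, 1, 0, 1)
        model = OpenSystemModel(
            H, coupling_from_generator(tridiagonal_generator(2, alpha, beta)), 0.5
        )
        out2 = 2.0 * master_rhs(model, rho)
        h = H.matrix
        comm = h @ rho - rho @ h
        expected = -1j * comm + np.diag(
            [alpha * rho[1, 1].real - beta * rho[0, 0].real,
             beta * rho[0, 0].real - alpha * rho[1, 1].real]
        )
        np.testing.assert_allclose(out2, expected, atol=1e-12)
        assert out2[1, 0] == pytest.approx(
            -1j * (2 * rho[0, 0] - 1 + rho[1, 0]), abs=1e-12
        )


class TestSuperoperator:
    @pytest.mark.parametrize("seed", range(10))
    def test_vec_consistency_with_master_rhs(self, seed, make_instance):
        H, K, G, rho = make_instance(seed + 100)
        w = [0.0, 0.25, 0.5, 0.75, 1.0][seed % 5]
        model = OpenSystemModel(H, G, w)
        S = build_superoperator(model)
        np.testing.assert_allclose(
            S.apply(rho.matrix), master_rhs(model, rho.matrix), atol=1e-10
        )

    def test_sparse_and_dense_agree(self, make_instance):
        H, K, G, rho = make_instance(42)
        model = OpenSystemModel(H, G, 0.5)
        dense = build_superoperator(model, sparse=False).matrix
        sparse = build_superoperator(model, sparse=True).matrix.toarray()
        np.testing.assert_allclose(dense, sparse, atol=1e-14)

    def test_pure_quantum_kron_form(self, make_instance):
        H, K, G, rho = make_instance(3)
        model = OpenSystemModel(H, G, 0.0)
        n = H.n_levels
        eye = np.eye(n)
        expected = -1j * (np.kron(eye, H.matrix) - np.kron(H.matrix.T, eye))
        np.testing.assert_allclose(
            build_superoperator(model).matrix, expected, atol=1e-13
        )

    def test_action_is_traceless(self, make_instance):
        for seed in range(5):
            H, K, G, rho = make_instance(seed + 200)
            model = OpenSystemModel(H, G, 0.6)
            out = build_superoperator(model).apply(rho.matrix)
            assert abs(np.trace(out)) < 1e-10


class TestPropagation:
    @pytest.mark.parametrize("seed", range(8))
    def test_expm_and_ode_routes_agree(self, seed, make_instance):
        H, K, G, rho = make_instance(seed + 300)
        w = [0.0, 0.25, 0.5, 0.75, 1.0][seed % 5]
        model = OpenSystemModel(H, G, w)
        t = 0.8
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PositivityWarning)
            a = propagate_density(model, rho, t, method="superop_expm")
            b = propagate_density(model, rho, t, method="ode")
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-6)

    def test_pure_quantum_limit_matches_unitary_conjugation(self, make_instance):
        H, K, G, rho = make_instance(17)
        model = OpenSystemModel(H, G, 0.0)
        t = 1.9
        a = propagate_density(model, rho, t)
        b = propagate_density_unitary(H, rho, t)
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-8)

    def test_full_dissipation_generator_coupling_is_markov_on_diagonal(
        self, make_instance
    ):
        H, K, G, rho = make_instance(23)
        model = OpenSystemModel(H, coupling_from_generator(K), 1.0)
        t = 1.4
        out = propagate_density(model, rho, t)
        classical = propagate(K, ProbabilityState(rho.diagonal), t)
        np.testing.assert_allclose(out.diagonal, classical.probs, atol=1e-8)
        # off-diagonals untouched: zero column sums mean no coherence damping
        n = K.n_levels
        mask = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(
            out.matrix[mask], rho.matrix[mask], atol=1e-8
        )

    def test_transition_coupling_damps_coherence_exponentially(self, make_instance):
        H, K, G, rho = make_instance(29)
        model = OpenSystemModel(H, coupling_from_transition(K, 0.6), 1.0)
        t = 2.0
        out = propagate_density(model, rho, t)
        n = K.n_levels
        mask = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(
            np.abs(out.matrix[mask]),
            np.abs(rho.matrix[mask]) * np.exp(-t),
            atol=1e-8,
        )

    def test_time_scale_correspondence(self, make_instance):
        """w=1 diagonal under G=T(tau) at time t equals the (T(tau)-I)/tau
        flow at time tau*t: identical distributions on rescaled clocks."""
        from openwalk.markov_walk import approximate_generator

        H, K, G, rho = make_instance(31)
        tau, t = 0.35, 1.7
        model = OpenSystemModel(H, coupling_from_transition(K, tau), 1.0)
        out = propagate_density(model, rho, t)
        Kapprox = approximate_generator(K, tau)
        classical = propagate(Kapprox, ProbabilityState(rho.diagonal), tau * t)
        np.testing.assert_allclose(out.diagonal, classical.probs, atol=1e-8)

    def test_trace_and_hermiticity_along_trajectory(self, make_instance):
        H, K, G, rho = make_instance(37)
        model = OpenSystemModel(H, G, 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PositivityWarning)
            traj = propagate_density_grid(model, rho, np.linspace(0.2, 3.0, 10))
        for r in traj:
            assert abs(np.trace(r.matrix) - 1.0) < 1e-8
            assert np.max(np.abs(r.matrix - r.matrix.conj().T)) < 1e-8

    def test_positive_coupling_preserves_positivity(self, make_instance):
        H, K, G, rho = make_instance(41)
        model = OpenSystemModel(H, coupling_from_transition(K, 0.5), 0.5)
        traj = propagate_density_grid(model, rho, np.linspace(0.3, 4.0, 8))
        for r in traj:
            assert r.min_eigenvalue() >= -1e-8

    def test_generator_coupling_positivity_violation_is_reported(self):
        """With G=K (not completely positive) the density can leave the
        PSD cone; the propagator flags this instead of passing silently."""
        # rates chosen so the stationary state itself is indefinite
        # (alpha*beta < (beta-alpha)^2)
        alpha, beta = 1.0, 5.0
        H = tridiagonal_hamiltonian(2, 0, 1, 0, 1)
        K = tridiagonal_generator(2, alpha, beta)
        model = OpenSystemModel(H, coupling_from_generator(K), 0.5)
        rho0 = DensityState(np.diag([1.0, 0.0]).astype(complex))
        with pytest.warns(PositivityWarning):
            out = propagate_density(model, rho0, 50.0)
        assert out.min_eigenvalue() < -1e-8
        assert out.allow_nonpositive


class TestEquilibrium:
    @pytest.mark.parametrize("alpha,beta", [(1.0, 2.0), (0.6, 1.9), (2.2, 0.9)])
    def test_generator_coupling_closed_form(self, alpha, beta):
        H = tridiagonal_hamiltonian(2, 0, 1, 0, 1)
        K = tridiagonal_generator(2, alpha, beta)
        model = OpenSystemModel(H, coupling_from_generator(K), 0.5)
        eq = equilibrium(model)
        np.testing.assert_allclose(
            eq.matrix, two_state_equilibrium_K(alpha, beta), atol=1e-10
        )

    @pytest.mark.parametrize("alpha,beta", [(1.0, 2.0), (0.6, 1.9), (2.2, 0.9)])
    def test_transition_coupling_closed_form(self, alpha, beta):
        H = tridiagonal_hamiltonian(2, 0, 1, 0, 1)
        K = tridiagonal_generator(2, alpha, beta)
        model = OpenSystemModel(H, coupling_from_transition(K, np.inf), 0.5)
        eq = equilibrium(model)
        np.testing.assert_allclose(
            eq.matrix, two_state_equilibrium_T(alpha, beta), atol=1e-10
        )

    def test_matches_long_time_integration(self):
        alpha, beta = 1.0, 2.0
        H = tridiagonal_hamiltonian(2, 0, 1, 0, 1)
        K = tridiagonal_generator(2, alpha, beta)
        rho0 = DensityState(np.diag([1.0, 0.0]).astype(complex))
        for coupling in (coupling_from_generator(K), coupling_from_transition(K, np.inf)):
            model = OpenSystemModel(H, coupling, 0.5)
            eq = equilibrium(model)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", PositivityWarning)
                late = propagate_density(model, rho0, 100.0, check_positivity=False)
            np.testing.assert_allclose(late.matrix, eq.matrix, atol=1e-6)

    def test_example_instantiation(self):
        # alpha=1, beta=2: G=K gives [[1/3,1/3],[1/3,2/3]], PSD since
        # alpha*beta >= (beta-alpha)^2; G=T gives diag (4/9, 5/9), rho21=(1+i)/18
        eqK = two_state_equilibrium_K(1.0, 2.0)
        np.testing.assert_allclose(eqK, [[1 / 3, 1 / 3], [1 / 3, 2 / 3]])
        assert np.linalg.eigvalsh(eqK)[0] >= 0
        eqT = two_state_equilibrium_T(1.0, 2.0)
        np.testing.assert_allclose(np.diag(eqT).real, [4 / 9, 5 / 9])
        assert eqT[1, 0] == pytest.approx((1 + 1j) / 18)

    def test_degenerate_stationary_set_reported(self):
        # pure quantum flow: every density commuting with H is stationary
        H = tridiagonal_hamiltonian(2, 0, 1, 0, 1)
        K = tridiagonal_generator(2, 1.0, 2.0)
        model = OpenSystemModel(H, coupling_from_generator(K), 0.0)
        with pytest.warns(UserWarning, match="dimension"):
            assert equilibrium(model) is None


class TestSequentialMeasurementOpen:
    def test_reduces_to_quantum_at_w_zero(self, make_instance):
        H, K, G, rho = make_instance(51)
        n = H.n_levels
        scale = EvidenceScale(n)
        model = OpenSystemModel(H, G, 0.0)
        M1 = projector_for_levels(scale, range(0, max(1, n // 2)))
        M2 = projector_for_levels(scale, [n - 1])
        sched = [(M1, 0.5), (M2, 1.2)]
        a = joint_response_probability_open(model, rho, sched)
        b = joint_response_probability_quantum(H, rho, sched)
        assert a == pytest.approx(b, abs=1e-10)

    def test_reduces_to_markov_at_w_one_generator_coupling(self, make_instance):
        H, K, G, rho = make_instance(53)
        n = H.n_levels
        scale = EvidenceScale(n)
        model = OpenSystemModel(H, coupling_from_generator(K), 1.0)
        M1 = projector_for_levels(scale, range(0, max(1, n // 2)))
        M2 = projector_for_levels(scale, [0])
        sched = [(M1, 0.4), (M2, 1.0)]
        a = joint_response_probability_open(model, rho, sched)
        b = joint_response_probability(K, ProbabilityState(rho.diagonal), sched)
        assert a == pytest.approx(b, abs=1e-9)

    def test_all_identity_projectors_are_certain(self, make_instance):
        H, K, G, rho = make_instance(59)
        n = H.n_levels
        eye = projector_for_levels(EvidenceScale(n), range(n))
        model = OpenSystemModel(H, G, 0.5)
        assert joint_response_probability_open(
            model, rho, [(eye, 0.5), (eye, 1.5)]
        ) == pytest.approx(1.0, abs=1e-10)
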