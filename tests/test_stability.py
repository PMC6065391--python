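import numpy as np
import pytest
from helpers import draw_consumption_matrix, random_competitive_system

from cprstab import (
    CommunityParameters,
    SpecialistCommunity,
    State,
    competitive_equilibrium,
    crossfeeding_rhs,
    gamma_condition,
    gershgorin_symmetric_check,
    hermitian_certificate,
    invasion_fitness,
    jacobian,
    rank_condition,
    rates_from_densities,
    simulate,
    specialist_jacobian,
    specialist_lambdas,
    spectrum,
    sufficient_production_bound,
)


def finite_difference_jacobian(params, R, S, h=1e-6):
    """Central differences of the crossfeeding RHS at (R, S)."""
    n_r, n_s = params.n_resources, params.n_consumers
    y0 = np.concatenate([R, S])

    def f(y):
        dR, dS = crossfeeding_rhs(State(R=y[:n_r], S=y[n_r:]), params)
        return np.concatenate([dR, dS])

    J = np.empty((n_r + n_s, n_r + n_s))
    for k in range(n_r + n_s):
        e = np.zeros_like(y0)
        e[k] = h
        J[:, k] = (f(y0 + e) - f(y0 - e)) / (2 * h)
    return J


class TestJacobian:
    def test_one_species_toy(self):
        J = jacobian([[1.0]], None, [1.0], [1.0], 1.0)
        np.testing.assert_allclose(J, [[-1.0, -1.0], [1.0, 0.0]])

    def test_matches_finite_differences_with_production_and_leaching(self, rng):
        for _ in range(5):
            n = 5
            C = draw_consumption_matrix(rng, n, n)
            P = rng.uniform(0, 0.2, (n, n))
            eta = rng.uniform(0, 0.3, n)
            R = rng.uniform(0.3, 1.0, n)
            S = rng.uniform(0.3, 1.0, n)
            # rates need not balance the system: only the Jacobian
            # structure matters here
            rho = rng.uniform(0.5, 1.0, n)
            mu = rng.uniform(0.5, 1.0, n)
            params = CommunityParameters(
                C=C, P=P, rho=rho, mu=mu, epsilon=0.6, eta=eta
            )
            J = jacobian(C, P, R, S, 0.6, mu=mu, eta=eta)
            J_fd = finite_difference_jacobian(params, R, S)
            np.testing.assert_allclose(J, J_fd, rtol=1e-5, atol=1e-6)

    def test_rectangular_blocks(self, rng):
        C = draw_consumption_matrix(rng, 5, 3)
        R = rng.uniform(0.3, 1, 5)
        S = rng.uniform(0.3, 1, 3)
        J = jacobian(C, None, R, S, 0.8)
        assert J.shape == (8, 8)
        np.testing.assert_allclose(J[:5, 5:], -R[:, None] * C)
        np.testing.assert_allclose(J[5:, :5], 0.8 * S[:, None] * C.T)

    def test_specialist_block_form(self, reciprocal_pair):
        comm = reciprocal_pair
        J = specialist_jacobian(comm)
        n = comm.n
        full = jacobian(comm.C, comm.P, comm.r * np.ones(n), comm.s * np.ones(n),
                        comm.epsilon)
        np.testing.assert_allclose(J, full)


class TestSpectrum:
    def test_toy_eigenvalues_match_quadratic_roots(self):
        spec = spectrum([[-1.0, -1.0], [1.0, 0.0]])
        expected = np.array([-0.5 + 0.8660254j, -0.5 - 0.8660254j])
        np.testing.assert_allclose(
            sorted(spec.eigenvalues, key=lambda z: z.imag),
            sorted(expected, key=lambda z: z.imag),
            atol=1e-6,
        )
        assert spec.max_real == pytest.approx(-0.5)
        assert spec.stable and not spec.marginal

    def test_sorted_descending_real(self):
        spec = spectrum(np.diag([-2.0, -1.0, -3.0]))
        np.testing.assert_allclose(spec.eigenvalues.real, [-1.0, -2.0, -3.0])

    def test_conjugate_pairs(self, rng):
        C, R, S, _, _ = random_competitive_system(rng, 6)
        spec = spectrum(jacobian(C, None, R, S, 1.0))
        lam = spec.eigenvalues
        np.testing.assert_allclose(
            np.sort(lam.imag), -np.sort(lam.imag)[::-1], atol=1e-9
        )


class TestSpecialistLambdas:
    def test_zero_production_gives_known_pair(self):
        comm = SpecialistCommunity(c=1, s=1, r=1, P=np.zeros((4, 4)))
        gd = specialist_lambdas(comm)
        np.testing.assert_allclose(gd.gammas, 0.0, atol=1e-14)
        np.testing.assert_allclose(
            np.sort(gd.all_lambdas.imag), [-np.sqrt(3) / 2] * 4 + [np.sqrt(3) / 2] * 4,
            atol=1e-12,
        )
        np.testing.assert_allclose(gd.all_lambdas.real, -0.5, atol=1e-12)

    def test_union_matches_full_jacobian_spectrum(self, rng):
        for symmetric in (True, False):
            P = rng.uniform(0, 0.1, (6, 6))
            if symmetric:
                P = (P + P.T) / 2
            comm = SpecialistCommunity(c=1.2, s=0.7, r=0.9, P=P, epsilon=0.8)
            from helpers import assert_spectra_match

            gd = specialist_lambdas(comm)
            full = np.linalg.eigvals(specialist_jacobian(comm))
            assert_spectra_match(gd.all_lambdas, full, atol=1e-8)

    def test_marginal_gamma_gives_zero_root(self):
        # gamma exactly at cr: discriminant is (cs)^2, one root at 0
        comm = SpecialistCommunity(c=1, s=1, r=0.5, P=0.5 * np.eye(3))
        gd = specialist_lambdas(comm)
        assert np.min(np.abs(gd.all_lambdas)) < 1e-12


class TestGammaCondition:
    def test_real_gamma_threshold_at_cr(self, reciprocal_pair):
        assert gamma_condition(0.9, reciprocal_pair)  # cr = 1
        assert not gamma_condition(1.1, reciprocal_pair)

    def test_agrees_with_root_signs_on_random_draws(self, rng):
        # sharp condition: true iff both mapped roots strictly stable
        agree = 0
        for _ in range(1000):
            c, s, r, eps = rng.uniform(0.2, 2.0, 4)
            gamma = complex(rng.uniform(-2, 2), rng.uniform(-2, 2))
            comm = SpecialistCommunity(c=c, s=s, r=r, P=np.zeros((2, 2)), epsilon=eps)
            cs = c * s
            disc = np.sqrt(cs**2 - 4 * eps * cs * (c * r - gamma) + 0j)
            roots = np.array([(-cs + disc) / 2, (-cs - disc) / 2])
            predicted = gamma_condition(gamma, comm)
            actual = bool(roots.real.max() < 0)
            agree += predicted == actual
        assert agree == 1000


class TestProductionBound:
    def test_zero_production_reduces_to_turnover_comparison(self):
        # passes iff cr > cs / (4 eps)
        fast = SpecialistCommunity(c=1, s=1, r=1, P=np.zeros((2, 2)))
        slow = SpecialistCommunity(c=1, s=1, r=0.2, P=np.zeros((2, 2)))
        assert sufficient_production_bound(fast).all_ok
        assert not sufficient_production_bound(slow).all_ok

    def test_hand_example(self, reciprocal_pair):
        report = sufficient_production_bound(reciprocal_pair)
        np.testing.assert_allclose(report.lhs, 0.16)
        np.testing.assert_allclose(report.rhs, 0.75)
        assert report.all_ok

    def test_bound_is_sufficient_not_necessary(self, rng):
        # witnesses: symmetric, feasible P that fail the bound yet are stable
        hollow = 0.3 * (np.ones((4, 4)) - np.eye(4))  # off-row sums 0.9 < cr
        witnesses = [hollow]
        for _ in range(500):
            P = rng.uniform(0, 0.3, (4, 4))
            P = (P + P.T) / 2
            comm = SpecialistCommunity(c=1, s=0.2, r=1, P=P, epsilon=1)
            if sufficient_production_bound(comm).all_ok:
                continue
            if np.all(comm.c * comm.r > P.sum(axis=1)):
                witnesses.append(P)
        assert len(witnesses) > 1  # the random search finds some too
        for P in witnesses:
            comm = SpecialistCommunity(c=1, s=0.2 if P is not hollow else 1.0,
                                       r=1, P=P, epsilon=1)
            assert not sufficient_production_bound(comm).all_ok
            assert spectrum(specialist_jacobian(comm)).stable


class TestGershgorin:
    def test_zero_production_passes(self):
        comm = SpecialistCommunity(c=1, s=1, r=1, P=np.zeros((3, 3)))
        assert gershgorin_symmetric_check(comm)

    def test_heavy_row_fails(self):
        P = np.full((2, 2), 0.55)
        comm = SpecialistCommunity(c=1, s=1, r=1, P=P)
        assert not gershgorin_symmetric_check(comm)

    def test_asymmetric_input_names_worst_entry(self):
        P = np.array([[0.0, 0.3], [0.1, 0.0]])
        comm = SpecialistCommunity(c=1, s=1, r=1, P=P)
        with pytest.raises(ValueError, match=r"2\.000e-01 at \(0, 1\)"):
            gershgorin_symmetric_check(comm)

    def test_certified_systems_are_stable(self, rng):
        for _ in range(100):
            P = rng.uniform(0, 0.2, (5, 5))
            P = (P + P.T) / 2
            comm = SpecialistCommunity(
                c=1.0, s=float(rng.uniform(0.1, 1)), r=float(rng.uniform(0.5, 1)),
                P=P,
            )
            if gershgorin_symmetric_check(comm):
                assert spectrum(specialist_jacobian(comm)).max_real < 0


class TestInvasionFitness:
    def test_resident_consumer_has_zero_fitness(self, rng):
        C, R, S, rho, mu = random_competitive_system(rng, 4)
        for j in range(4):
            assert invasion_fitness(C, R, mu, 1.0, j) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("factor, sign", [(1.1, -1), (0.9, +1)])
    def test_sign_matches_simulated_invasion(self, rng, factor, sign):
        # resident pair at equilibrium; third consumer's mortality set
        # 10% above (below) its break-even rate
        C = draw_consumption_matrix(rng, 3, 3)
        R = rng.uniform(0.3, 1, 3)
        S_resident = np.array([0.5, 0.5, 0.0])
        rho_full, mu_full = rates_from_densities(C, R, np.array([0.5, 0.5, 0.4]), 1.0)
        mu = mu_full.copy()
        mu[2] = factor * (C.T @ R)[2]
        fit = invasion_fitness(C, R, mu, 1.0, 2)
        assert np.sign(fit) == sign
        # re-balance rho for the two residents, introduce a tiny invader
        rho = R * (C @ S_resident)
        params = CommunityParameters(C=C, rho=rho, mu=mu)
        s0 = 1e-4
        traj = simulate(
            params, State(R=R, S=[0.5, 0.5, s0]), np.linspace(0, 5, 6),
            rhs="competition",
        )
        grew = traj.S[-1, 2] > s0
        assert grew == (sign > 0)


class TestRankCondition:
    def test_identity_full_rank(self):
        report = rank_condition(np.eye(3))
        assert report.rank == 3 and report.condition_holds

    def test_duplicate_columns_detected(self):
        C = np.array([[1.0, 1.0], [0.5, 0.5]])
        report = rank_condition(C)
        assert report.rank == 1 and not report.condition_holds

    def test_rectangular_full_column_rank(self, rng):
        C = draw_consumption_matrix(rng, 4, 3)
        assert rank_condition(C).condition_holds


class TestHermitianCertificate:
    def test_identity_at_zero(self):
        assert hermitian_certificate(np.eye(2), [1, 1], [1, 1], 1.0, 0.0)

    def test_holds_across_right_half_plane(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 8))
            C, R, S, _, _ = random_competitive_system(rng, n)
            lam = complex(rng.uniform(0, 10), rng.uniform(-5, 5))
            assert hermitian_certificate(C, R, S, 1.0, lam)

    def test_fails_for_rank_deficient_matrix(self):
        C = np.array([[1.0, 1.0], [0.4, 0.4]])
        assert not hermitian_certificate(C, [1, 1], [1, 1], 1.0, 0.5)

    def test_rejects_left_half_plane_query(self):
        with pytest.raises(ValueError, match="Re"):
            hermitian_certificate(np.eye(2), [1, 1], [1, 1], 1.0, -1.0)
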