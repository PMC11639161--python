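import numpy as np
import pytest

from groupknock import (
    CorrelationModel,
    SolverOptions,
    ValidationError,
    conditional_knockoff_law,
    conditional_regressions,
    regularize,
    sample_ghost_zscores,
    sample_knockoffs_gaussian,
    sample_knockoffs_group_key,
    solve_group_knockoff,
)
from groupknock.grouping import partition_from_labels
from groupknock.solver import assemble_gs

from conftest import make_ci_model, random_correlation


def _implied_joint_cov(sigma, P, V, m):
    """Joint covariance of (Z, PZ + eps_1, ..., PZ + eps_m) assembled directly."""
    p = sigma.shape[0]
    G = np.zeros(((m + 1) * p, (m + 1) * p))
    G[:p, :p] = sigma
    PSP = P @ sigma @ P.T
    for k in range(m):
        rk = slice((k + 1) * p, (k + 2) * p)
        G[rk, :p] = P @ sigma
        G[:p, rk] = (P @ sigma).T
        for l in range(m):
            rl = slice((l + 1) * p, (l + 2) * p)
            G[rk, rl] = PSP + V[k * p:(k + 1) * p, l * p:(l + 1) * p]
    return G


class TestConditionalLaw:
    def test_s_zero_copies_originals(self, rng):
        sigma = random_correlation(rng, 4)
        P, V = conditional_knockoff_law(sigma, np.zeros((4, 4)), 2)
        np.testing.assert_allclose(P, np.eye(4), atol=1e-12)
        np.testing.assert_allclose(V, np.zeros((8, 8)), atol=1e-12)

    def test_identity_sigma_full_s_gives_independent_knockoffs(self):
        P, V = conditional_knockoff_law(np.eye(3), np.eye(3), 1)
        np.testing.assert_allclose(P, np.zeros((3, 3)), atol=1e-12)
        np.testing.assert_allclose(V, np.eye(3), atol=1e-12)

    def test_reconstructs_joint_covariance(self, rng):
        sigma = random_correlation(rng, 4)
        model = regularize(CorrelationModel(sigma=sigma))
        part = partition_from_labels([0, 0, 1, 1])
        sol = solve_group_knockoff(model, part, SolverOptions(method="maxent", m=3))
        P, V = conditional_knockoff_law(model.sigma, sol.S, 3)
        G = _implied_joint_cov(model.sigma, P, V, 3)
        np.testing.assert_allclose(G, assemble_gs(model.sigma, sol.S, 3), atol=1e-10)

    def test_infeasible_s_rejected(self):
        with pytest.raises(ValidationError):
            conditional_knockoff_law(np.eye(2), 3.0 * np.eye(2), 1)


class TestGaussianSampler:
    def test_s_zero_returns_exact_copies(self, rng):
        sigma = random_correlation(rng, 3)
        X = rng.standard_normal((5, 3))
        ks = sample_knockoffs_gaussian(X, sigma, np.zeros((3, 3)), 2, seed=0)
        np.testing.assert_allclose(ks.copy(1), X, atol=1e-10)
        np.testing.assert_allclose(ks.copy(2), X, atol=1e-10)

    def test_seed_reproducibility(self, rng):
        sigma = random_correlation(rng, 3)
        X = rng.standard_normal((10, 3))
        a = sample_knockoffs_gaussian(X, sigma, 0.5 * np.eye(3), 2, seed=7)
        b = sample_knockoffs_gaussian(X, sigma, 0.5 * np.eye(3), 2, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empirical_cross_covariance_matches_sigma_minus_s(self, rng):
        p, m, n = 4, 2, 200_000
        sigma = random_correlation(rng, p)
        model = regularize(CorrelationModel(sigma=sigma))
        part = partition_from_labels([0, 0, 1, 1])
        sol = solve_group_knockoff(model, part, SolverOptions(method="maxent", m=m))
        L = np.linalg.cholesky(model.sigma)
        X = rng.standard_normal((n, p)) @ L.T
        ks = sample_knockoffs_gaussian(X, model.sigma, sol.S, m, seed=11)
        for k in (1, 2):
            emp = X.T @ ks.copy(k) / n
            np.testing.assert_allclose(emp, model.sigma - sol.S, atol=0.02)

    def test_swap_exchangeability_of_second_moments(self, rng):
        # swapping a whole group with its knockoffs leaves Cov(X, X~) invariant
        p, n = 4, 200_000
        sigma = random_correlation(rng, p)
        model = regularize(CorrelationModel(sigma=sigma))
        part = partition_from_labels([0, 0, 1, 1])
        sol = solve_group_knockoff(model, part, SolverOptions(method="maxent", m=1))
        L = np.linalg.cholesky(model.sigma)
        X = rng.standard_normal((n, p)) @ L.T
        ks = sample_knockoffs_gaussian(X, model.sigma, sol.S, 1, seed=3)
        J = np.hstack([X, ks.copy(1)])
        swapped = J.copy()
        g = part.groups[0]
        swapped[:, g], swapped[:, g + p] = J[:, g + p], J[:, g].copy()
        cov_a = J.T @ J / n
        cov_b = swapped.T @ swapped / n
        np.testing.assert_allclose(cov_a, cov_b, atol=0.02)


class TestGhostSampler:
    def test_s_zero_repeats_z(self, rng):
        sigma = random_correlation(rng, 3)
        z = rng.standard_normal(3)
        ks = sample_ghost_zscores(z, sigma, np.zeros((3, 3)), 3, seed=0)
        np.testing.assert_allclose(ks.values, np.tile(z, 3), atol=1e-10)

    def test_identity_case_independent_standard_normal(self, rng):
        # Sigma = S = I: knockoff z-scores ignore z entirely
        z = np.array([5.0, -3.0])
        reps = np.stack([
            sample_ghost_zscores(z, np.eye(2), np.eye(2), 2, seed=s).values
            for s in range(4000)
        ])
        assert np.abs(reps.mean(axis=0)).max() < 0.08
        corr = np.corrcoef(reps, rowvar=False)
        assert np.abs(corr - np.eye(4)).max() < 0.08

    def test_determinism(self, rng):
        sigma = random_correlation(rng, 3)
        z = rng.standard_normal(3)
        a = sample_ghost_zscores(z, sigma, 0.3 * np.eye(3), 2, seed=5).values
        b = sample_ghost_zscores(z, sigma, 0.3 * np.eye(3), 2, seed=5).values
        np.testing.assert_array_equal(a, b)


class TestGroupKeySampler:
    def test_all_keys_reduces_to_plain_sampler(self, rng):
        sigma = random_correlation(rng, 6)
        model = regularize(CorrelationModel(sigma=sigma))
        part = partition_from_labels([0, 0, 0, 1, 1, 1])
        from groupknock import select_key_variables

        keys = select_key_variables(model, part, c=1.0)
        regs = conditional_regressions(model, keys)
        sol = solve_group_knockoff(model, part, SolverOptions(method="maxent", m=2))
        X = rng.standard_normal((20, 6))
        via_keys = sample_knockoffs_group_key(X, model, keys, regs, sol, 2, seed=9)
        plain = sample_knockoffs_gaussian(X, model.sigma, sol.S, 2, seed=9)
        np.testing.assert_array_equal(via_keys.values, plain.values)

    def test_ghost_route_shapes_and_determinism(self, rng):
        model, part, keys = make_ci_model(rng, [4, 4], [2, 2])
        regs = conditional_regressions(model, keys)
        key_idx = keys.key_indices
        sub = CorrelationModel(sigma=model.sigma[np.ix_(key_idx, key_idx)])
        sub_part = partition_from_labels(part.assignment[key_idx])
        sol = solve_group_knockoff(sub, sub_part, SolverOptions(method="maxent", m=3))
        z = rng.standard_normal(8)
        a = sample_knockoffs_group_key(z, model, keys, regs, sol, 3, seed=1)
        b = sample_knockoffs_group_key(z, model, keys, regs, sol, 3, seed=1)
        assert a.values.shape == (24,)
        np.testing.assert_array_equal(a.values, b.values)

    def test_ci_construction_matches_full_solve_covariance(self, rng):
        # on a CI-structured Sigma the key-route maxent knockoffs reproduce
        # the full-Sigma maxent joint covariance (distributional equivalence)
        model, part, keys = make_ci_model(rng, [4, 4, 4], [2, 2, 2])
        regs = conditional_regressions(model, keys)
        opts = SolverOptions(method="maxent", m=1, tol_obj=1e-10, max_sweeps=300)
        full = solve_group_knockoff(model, part, opts)
        key_idx = keys.key_indices
        sub = CorrelationModel(sigma=model.sigma[np.ix_(key_idx, key_idx)])
        sub_part = partition_from_labels(part.assignment[key_idx])
        sol_star = solve_group_knockoff(sub, sub_part, opts)
        n = 200_000
        L = np.linalg.cholesky(model.sigma)
        X = rng.standard_normal((n, 12)) @ L.T
        ks = sample_knockoffs_group_key(X, model, keys, regs, sol_star, 1, seed=2)
        J = np.hstack([X, ks.values])
        emp = J.T @ J / n
        np.testing.assert_allclose(emp, full.materialize_gs(), atol=0.02)
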