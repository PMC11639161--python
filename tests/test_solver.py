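import numpy as np
import pytest

from groupknock import (
    CorrelationModel,
    SolverOptions,
    ValidationError,
    assemble_gs,
    objective,
    regularize,
    solve_equi,
    solve_group_knockoff,
)
from groupknock.grouping import partition_from_labels
from groupknock.solver import (
    SolverState,
    apply_update,
    feasible_interval,
    generic_coordinate_update,
    me_coordinate_update,
    pca_update,
)

from conftest import random_correlation


def _state(sigma, labels, S0, m=1):
    return SolverState(sigma, partition_from_labels(labels), S0, m)


def _toy_state():
    """Sigma = I_2, S = 0.5 I, m = 1 (so D = 1.5 I), one group of two."""
    return _state(np.eye(2), [0, 0], 0.5 * np.eye(2), m=1)


class TestObjective:
    def test_sdp_zero_at_sigma(self):
        part = partition_from_labels([0, 0])
        assert objective(np.eye(2), np.eye(2), 1, "sdp", part) == 0.0

    def test_maxent_scalar_form(self):
        # p=1: loss is -[log s + log(2 - s)], minimized at s = 1
        vals = [objective(np.array([[s]]), np.eye(1), 1, "maxent") for s in (0.5, 1.0, 1.5)]
        assert vals[1] == pytest.approx(0.0, abs=1e-12)
        assert vals[0] > vals[1] < vals[2]
        assert vals[0] == pytest.approx(-(np.log(0.5) + np.log(1.5)))

    def test_mvr_identity_case(self):
        assert objective(np.eye(2), np.eye(2), 1, "mvr") == pytest.approx(4.0)

    def test_singular_s_gives_infinite_loss(self):
        assert objective(np.zeros((2, 2)), np.eye(2), 1, "maxent") == np.inf

    def test_maxent_logdet_identity(self, rng):
        # logdet(G_S) = m logdet(S) + logdet(D) + p log m on random instances
        for m in (1, 2, 3):
            sigma = random_correlation(rng, 4)
            S = 0.3 * np.diag(np.diag(sigma))
            G = assemble_gs(sigma, S, m)
            direct = np.linalg.slogdet(G)[1]
            D = ((m + 1) / m) * sigma - S
            block = m * np.linalg.slogdet(S)[1] + np.linalg.slogdet(D)[1] + 4 * np.log(m)
            assert direct == pytest.approx(block, rel=1e-10)

    def test_mvr_trace_identity(self, rng):
        # Tr(G_S^-1) via the block formula vs direct (m+1)p inversion
        for m in (1, 2, 3):
            sigma = random_correlation(rng, 6)
            S = 0.4 * np.eye(6)
            direct = np.trace(np.linalg.inv(assemble_gs(sigma, S, m)))
            assert objective(S, sigma, m, "mvr") == pytest.approx(direct, rel=1e-10)


class TestEqui:
    def test_identity_sigma(self):
        model = CorrelationModel(sigma=np.eye(4))
        sol = solve_equi(model, partition_from_labels(range(4)), m=1)
        assert sol.gamma_equi == pytest.approx(1.0)
        np.testing.assert_allclose(sol.S / (1 - sol.eps_boundary), np.eye(4), atol=1e-12)

    def test_single_group_whitens_to_identity(self, rng):
        sigma = random_correlation(rng, 5)
        model = CorrelationModel(sigma=sigma)
        sol = solve_equi(model, partition_from_labels([0] * 5), m=1)
        assert sol.gamma_equi == pytest.approx(1.0)
        np.testing.assert_allclose(sol.S / (1 - sol.eps_boundary), sigma, atol=1e-10)

    def test_equicorrelated_tau(self):
        # lambda_min of an equicorrelated correlation matrix is 1 - rho
        sigma = 0.75 + 0.25 * np.eye(6)
        sol = solve_equi(CorrelationModel(sigma=sigma), partition_from_labels(range(6)), m=1)
        assert sol.gamma_equi == pytest.approx(0.5, abs=1e-12)


class TestFeasibleInterval:
    def test_diagonal_toy_values(self):
        lo, hi = feasible_interval(_toy_state(), 0, 0)
        assert (lo, hi) == (pytest.approx(-0.5), pytest.approx(1.5))

    def test_offdiagonal_toy_values(self):
        lo, hi = feasible_interval(_toy_state(), 0, 1)
        assert (lo, hi) == (pytest.approx(-0.5), pytest.approx(1.5))

    def test_interval_contains_zero_on_random_states(self, rng):
        sigma = random_correlation(rng, 6)
        state = _state(sigma, [0, 0, 0, 1, 1, 1], 0.3 * np.eye(6), m=2)
        for (i, j) in [(0, 0), (0, 2), (3, 5), (4, 4)]:
            lo, hi = feasible_interval(state, i, j)
            assert lo < 0 < hi

    def test_cross_group_entry_rejected(self):
        state = _state(np.eye(4), [0, 0, 1, 1], 0.5 * np.eye(4))
        with pytest.raises(ValidationError):
            feasible_interval(state, 0, 3)


class TestCoordinateUpdates:
    def test_me_diagonal_closed_form(self):
        # s = (S^-1)_11 = 2, d = (D^-1)_11 = 2/3 -> delta = 0.5
        assert me_coordinate_update(_toy_state(), 0, 0, m=1) == pytest.approx(0.5, abs=1e-9)

    def test_me_diagonal_matches_grid_search(self, rng):
        sigma = random_correlation(rng, 4)
        state = _state(sigma, [0, 0, 1, 1], 0.4 * np.eye(4), m=2)
        delta = me_coordinate_update(state, 1, 1, m=2)
        a = state.quads_S([1])[0, 0]
        d = state.quads_D([1])[0, 0]
        grid = np.linspace(-1 / a + 1e-4, 1 / d - 1e-4, 40001)
        g = 2 * np.log(1 + grid * a) + np.log(1 - grid * d)
        assert delta == pytest.approx(grid[np.argmax(g)], abs=1e-3)

    def test_me_zero_at_optimum(self):
        state = _state(np.eye(2), [0, 0], np.eye(2) * (1 - 1e-9))
        assert me_coordinate_update(state, 0, 0, m=1) == pytest.approx(0.0, abs=1e-6)
        assert me_coordinate_update(state, 0, 1, m=1) == pytest.approx(0.0, abs=1e-5)

    def test_sdp_moves_entry_to_target(self):
        assert generic_coordinate_update(_toy_state(), 0, 0, 1, "sdp") == pytest.approx(0.5, abs=1e-9)

    def test_mvr_scalar_optimum(self):
        state = _state(np.eye(1), [0], np.array([[0.5]]), m=1)
        assert generic_coordinate_update(state, 0, 0, 1, "mvr") == pytest.approx(0.5, abs=1e-6)

    def test_updates_vanish_at_converged_solution(self, rng):
        sigma = random_correlation(rng, 6)
        model = regularize(CorrelationModel(sigma=sigma))
        part = partition_from_labels([0, 0, 0, 1, 1, 1])
        for method in ("maxent", "mvr"):
            sol = solve_group_knockoff(
                model, part, SolverOptions(method=method, m=1, tol_obj=1e-12, max_sweeps=300)
            )
            state = SolverState(model.sigma, part, sol.S, 1)
            for (i, j) in [(0, 0), (0, 2), (4, 4), (3, 5)]:
                if method == "maxent":
                    d = me_coordinate_update(state, i, j, 1)
                else:
                    d = generic_coordinate_update(state, i, j, 1, method)
                assert abs(d) < 5e-4


class TestPcaUpdates:
    def test_maxent_basis_vector_closed_form(self):
        delta = pca_update(_toy_state(), np.array([1.0, 0.0]), 1, "maxent")
        assert delta == pytest.approx(0.5, abs=1e-9)

    def test_zero_at_optimum(self):
        state = _state(np.eye(2), [0, 0], np.eye(2) * (1 - 1e-9))
        assert pca_update(state, np.array([1.0, 0.0]), 1, "maxent") == pytest.approx(0.0, abs=1e-6)

    def test_step_inside_rank_one_interval(self, rng):
        sigma = random_correlation(rng, 5)
        state = _state(sigma, [0] * 5, 0.3 * sigma, m=1)
        w, V = np.linalg.eigh(sigma)
        for k in range(5):
            v = V[:, k]
            a_s, _ = state.quad_vec(state.C, v)
            a_d, _ = state.quad_vec(state.L, v)
            for method in ("maxent", "mvr", "sdp"):
                delta = pca_update(state, v, 1, method)
                assert -1 / a_s < delta < 1 / a_d

    def test_diagonal_coordinate_equals_basis_pca_for_maxent(self, rng):
        # both reduce to (m s - d)/((m+1) s d)
        sigma = random_correlation(rng, 4)
        state = _state(sigma, [0, 0, 1, 1], 0.4 * np.eye(4), m=3)
        e2 = np.zeros(4)
        e2[2] = 1.0
        assert me_coordinate_update(state, 2, 2, 3) == pytest.approx(
            pca_update(state, e2, 3, "maxent"), abs=1e-10
        )

    def test_cross_block_direction_rejected(self):
        state = _state(np.eye(4), [0, 0, 1, 1], 0.5 * np.eye(4))
        with pytest.raises(ValidationError):
            pca_update(state, np.ones(4) / 2.0, 1, "maxent")


class TestApplyUpdate:
    def test_zero_delta_is_noop(self):
        state = _toy_state()
        S_before = state.S.copy()
        apply_update(state, 0.0, i=0, j=0)
        np.testing.assert_array_equal(state.S, S_before)

    def test_diagonal_update_matches_refactorization(self):
        state = _toy_state()
        apply_update(state, 0.5, i=0, j=0)
        np.testing.assert_allclose(state.C, np.linalg.cholesky(np.diag([1.0, 0.5])), atol=1e-12)
        np.testing.assert_allclose(state.L, np.linalg.cholesky(np.diag([1.0, 1.5])), atol=1e-12)

    def test_hundred_random_updates_keep_factors_exact(self, rng):
        from groupknock.solver import _exact_offdiag_interval, _sigma_block

        sigma = random_correlation(rng, 8)
        part = partition_from_labels([0] * 4 + [1] * 4)
        state = SolverState(sigma, part, 0.3 * _sigma_block(sigma, part), m=1)
        for _ in range(100):
            g = part.groups[rng.integers(2)]
            i, j = sorted(rng.choice(g, size=2, replace=True))
            if i == j:
                lo, hi = feasible_interval(state, i, i)
            else:
                lo, hi = _exact_offdiag_interval(state.quads_S([i, j]), state.quads_D([i, j]))
            delta = rng.uniform(0.25 * lo, 0.25 * hi)
            apply_update(state, delta, i=i, j=j)
        assert state.factor_error() <= 1e-8


class TestSolve:
    @pytest.mark.parametrize("method", ["maxent", "mvr", "sdp", "equi"])
    @pytest.mark.parametrize("m", [1, 5])
    def test_identity_sigma_gives_identity_s(self, method, m):
        model = CorrelationModel(sigma=np.eye(6))
        part = partition_from_labels(range(6))
        sol = solve_group_knockoff(model, part, SolverOptions(method=method, m=m))
        S = sol.S / (1 - sol.eps_boundary) if method == "equi" else sol.S
        np.testing.assert_allclose(S, np.eye(6), atol=1e-6)

    @pytest.mark.parametrize("method", ["maxent", "mvr", "sdp"])
    def test_single_group_recovers_sigma(self, method, rng):
        sigma = random_correlation(rng, 6)
        model = regularize(CorrelationModel(sigma=sigma))
        part = partition_from_labels([0] * 6)
        sol = solve_group_knockoff(
            model, part, SolverOptions(method=method, m=1, tol_obj=1e-10, max_sweeps=500)
        )
        np.testing.assert_allclose(sol.S, model.sigma, atol=1e-4)

    @pytest.mark.parametrize("method", ["maxent", "mvr", "sdp"])
    def test_trace_monotone_and_feasible(self, method, rng):
        sigma = random_correlation(rng, 6)
        model = regularize(CorrelationModel(sigma=sigma))
        part = partition_from_labels([0, 0, 0, 1, 1, 1])
        sol = solve_group_knockoff(model, part, SolverOptions(method=method, m=2))
        trace = np.array(sol.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9)
        lam_s, lam_d = sol.slack
        assert lam_s >= -1e-8 and lam_d >= -1e-8
        # S respects the block pattern
        off = sol.S.copy()
        for g in part.groups:
            off[np.ix_(g, g)] = 0.0
        assert np.abs(off).max() == 0.0

    def test_iterative_sdp_dominates_equivariant(self, rng):
        sigma = random_correlation(rng, 6)
        model = regularize(CorrelationModel(sigma=sigma))
        part = partition_from_labels([0, 0, 0, 1, 1, 1])
        sdp = solve_group_knockoff(model, part, SolverOptions(method="sdp", m=1))
        equi = solve_equi(model, part, m=1)
        obj_sdp = objective(sdp.S, model.sigma, 1, "sdp", part)
        obj_equi = objective(equi.S, model.sigma, 1, "sdp", part)
        assert obj_sdp <= obj_equi + 1e-8
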