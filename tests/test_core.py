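import numpy as np
import pytest
import scipy.optimize

from dishare.core import (
    CohortPair,
    FitOptions,
    Formulation,
    PenaltySpec,
    RSQRT2,
    SharedFit,
    build_stacked_design,
    evaluate_objective,
    fit_shared,
    kkt_violation,
    lambda_max_value,
    objective_terms,
    predict_shared,
    solve_weighted_enet,
    transform_formulations,
)

from conftest import random_pair


# ---------------------------------------------------------------------------
# CohortPair / PenaltySpec validation


class TestCohortPair:
    def test_column_mismatch_names_block(self):
        with pytest.raises(ValueError, match="X_G and X_C"):
            CohortPair(np.ones((2, 3)), np.ones(2), np.ones((2, 4)), np.ones(2))

    def test_response_length_mismatch(self):
        with pytest.raises(ValueError, match="y_C"):
            CohortPair(np.ones((2, 3)), np.ones(2), np.ones((2, 3)), np.ones(3))

    def test_nan_rejected(self):
        X = np.ones((2, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="X_G"):
            CohortPair(X, np.ones(2), np.ones((2, 2)), np.ones(2))

    def test_duplicate_feature_names(self):
        with pytest.raises(ValueError, match="unique"):
            CohortPair(
                np.ones((2, 2)), np.ones(2), np.ones((2, 2)), np.ones(2),
                feature_names=("a", "a"),
            )

    def test_one_empty_cohort_allowed(self):
        pair = CohortPair(np.ones((3, 2)), np.ones(3), np.zeros((0, 2)), np.zeros(0))
        assert pair.n_C == 0 and pair.p == 2

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one cohort"):
            CohortPair(np.zeros((0, 2)), np.zeros(0), np.zeros((0, 2)), np.zeros(0))


class TestPenaltySpec:
    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            PenaltySpec(-1.0, 0.0)

    def test_default_r(self):
        assert PenaltySpec(1.0, 1.0).r == pytest.approx(1 / np.sqrt(2))

    def test_infinite_weights_allowed(self):
        spec = PenaltySpec(1.0, 0.0, omega=np.array([np.inf, 1.0]))
        assert np.isinf(spec.omega[0])


# ---------------------------------------------------------------------------
# objective


class TestObjective:
    def test_zero_coefficients_loss_only(self):
        # y_G=(1,1), y_C=(2,), beta=delta=0 -> 1/2 (1 + 1 + 4) = 3
        pair = CohortPair(
            np.zeros((2, 2)), np.array([1.0, 1.0]),
            np.zeros((1, 2)), np.array([2.0]),
        )
        val = evaluate_objective(
            pair, PenaltySpec(1.0, 1.0), beta=np.zeros(2), delta=np.zeros(2)
        )
        assert val == pytest.approx(3.0)

    def test_penalty_only_case(self):
        pair = CohortPair(
            np.zeros((2, 2)), np.zeros(2), np.zeros((2, 2)), np.zeros(2)
        )
        pen = PenaltySpec(2.0, 1.0, r=RSQRT2, omega=np.ones(2), psi=np.ones(2))
        val = evaluate_objective(
            pair, pen, beta=np.array([1.0, 0.0]), delta=np.array([0.0, 1.0])
        )
        assert val == pytest.approx(3.0 * (1.0 + RSQRT2), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_term_by_term_sum(self, seed):
        # independent brute-force evaluation, scalar loops only
        rng = np.random.default_rng(seed)
        p, n_G, n_C = 4, 6, 6
        pair, _, _ = random_pair(seed, n_G=n_G, n_C=n_C, p=p)
        beta = rng.standard_normal(p)
        delta = rng.standard_normal(p)
        omega = rng.uniform(0.1, 2.0, p)
        psi = rng.uniform(0.1, 2.0, p)
        l1, l2, r = rng.uniform(0.1, 2.0, 3)
        pen = PenaltySpec(l1, l2, r=r, omega=omega, psi=psi)

        expected = 0.0
        for i in range(n_G):
            resid = pair.y_G[i] - sum(pair.X_G[i, j] * beta[j] for j in range(p))
            expected += 0.5 * resid**2
        for i in range(n_C):
            resid = pair.y_C[i] - sum(
                pair.X_C[i, j] * (beta[j] + delta[j]) for j in range(p)
            )
            expected += 0.5 * resid**2
        for j in range(p):
            expected += l1 * (omega[j] * abs(beta[j]) + r * psi[j] * abs(delta[j]))
            expected += l2 * (beta[j] ** 2 + r * delta[j] ** 2)

        got = evaluate_objective(pair, pen, beta=beta, delta=delta)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_asymmetric_loss_convention(self):
        pair = CohortPair(
            np.zeros((2, 1)), np.array([1.0, 1.0]),
            np.zeros((1, 1)), np.array([2.0]),
        )
        val = evaluate_objective(
            pair, PenaltySpec(0.0, 0.0), beta=np.zeros(1), delta=np.zeros(1),
            loss="g_half_only",
        )
        assert val == pytest.approx(0.5 * 2 + 4.0)

    def test_decomposition_retrievable(self, small_pair):
        pen = PenaltySpec(0.5, 0.2)
        beta = np.ones(small_pair.p)
        delta = np.ones(small_pair.p) * 0.1
        terms = objective_terms(small_pair, pen, beta=beta, delta=delta)
        total = evaluate_objective(small_pair, pen, beta=beta, delta=delta)
        assert set(terms) == {"loss", "l1", "l2"}
        assert total == pytest.approx(terms["loss"] + terms["l1"] + terms["l2"])

    def test_infinite_weight_nonzero_coefficient_errors(self, small_pair):
        pen = PenaltySpec(
            1.0, 0.0, omega=np.r_[np.inf, np.ones(small_pair.p - 1)]
        )
        with pytest.raises(ValueError, match="infinite weight"):
            evaluate_objective(
                small_pair, pen,
                beta=np.ones(small_pair.p), delta=np.zeros(small_pair.p),
            )

    def test_dimension_mismatch_names_offender(self, small_pair):
        with pytest.raises(ValueError, match="beta"):
            evaluate_objective(
                small_pair, PenaltySpec(1.0, 0.0),
                beta=np.zeros(small_pair.p + 1), delta=np.zeros(small_pair.p),
            )


# ---------------------------------------------------------------------------
# stacked design


class TestStackedDesign:
    def test_f1_structure(self):
        rng = np.random.default_rng(1)
        X_G = rng.standard_normal((2, 2))
        X_C = rng.standard_normal((1, 2))
        pair = CohortPair(X_G, np.zeros(2), X_C, np.zeros(1))
        design = build_stacked_design(pair, Formulation.F1)
        assert design.Z.shape == (3, 4)
        np.testing.assert_array_equal(design.Z[:2, 2:], np.zeros((2, 2)))
        np.testing.assert_array_equal(design.Z[2, :2], X_C[0])
        np.testing.assert_array_equal(design.Z[2, 2:], X_C[0])
        assert design.blocks["beta"] == slice(0, 2)
        assert design.blocks["delta"] == slice(2, 4)

    def test_f2_structure(self):
        pair, _, _ = random_pair(2, n_G=3, n_C=4, p=2)
        design = build_stacked_design(pair, Formulation.F2)
        assert design.Z.shape == (7, 6)
        np.testing.assert_array_equal(design.Z[:3, 4:], np.zeros((3, 2)))
        np.testing.assert_array_equal(design.Z[3:, 2:4], np.zeros((4, 2)))
        np.testing.assert_array_equal(design.Z[3:, 4:], pair.X_C)

    def test_delta_zero_collapses_to_pooled_design(self):
        pair, _, _ = random_pair(3, p=4)
        design = build_stacked_design(pair, Formulation.F1)
        beta = np.random.default_rng(0).standard_normal(4)
        coef = np.r_[beta, np.zeros(4)]
        pooled = np.vstack([pair.X_G, pair.X_C])
        np.testing.assert_allclose(design.Z @ coef, pooled @ beta, atol=1e-12)

    def test_unknown_formulation_errors(self, small_pair):
        with pytest.raises(ValueError):
            build_stacked_design(small_pair, "F3")

    def test_response_stacking(self, small_pair):
        design = build_stacked_design(small_pair)
        np.testing.assert_array_equal(
            design.y, np.r_[small_pair.y_G, small_pair.y_C]
        )


# ---------------------------------------------------------------------------
# solver


def _oracle_objective(Z, y, coef, e1, e2):
    resid = y - Z @ coef
    return 0.5 * resid @ resid + np.sum(e1 * np.abs(coef)) + np.sum(e2 * coef**2)


def _lbfgs_oracle(Z, y, e1, e2):
    """Split-variable (theta = u - v, u,v >= 0) smooth reformulation."""
    m = Z.shape[1]

    def fun(x):
        u, v = x[:m], x[m:]
        coef = u - v
        resid = y - Z @ coef
        val = 0.5 * resid @ resid + e1 @ (u + v) + e2 @ coef**2
        grad_c = -(Z.T @ resid) + 2 * e2 * coef
        return val, np.r_[grad_c + e1, -grad_c + e1]

    x0 = np.zeros(2 * m)
    res = scipy.optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * m),
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10},
    )
    coef = res.x[:m] - res.x[m:]
    return _oracle_objective(Z, y, coef, e1, e2)


class TestSolver:
    def test_one_dimensional_closed_form(self):
        # 1/2 sum (y - x b)^2 + |b| + 0.5 b^2 with x=(1,1), y=(3,1)
        # rho = x'y = 4, a = 2 -> b = (4 - 1) / (2 + 2*0.5) = 1
        Z = np.array([[1.0], [1.0]])
        y = np.array([3.0, 1.0])
        sol = solve_weighted_enet(
            Z, y, np.ones(1), np.ones(1), lambda1=1.0, lambda2=0.5
        )
        assert sol.converged
        assert sol.coef[0] == pytest.approx(1.0, abs=1e-10)

    def test_lambda_max_gives_all_zero(self):
        pair, _, _ = random_pair(4, p=5)
        design = build_stacked_design(pair)
        l1_w, l2_w = design.weight_vectors(PenaltySpec(0.0, 0.0))
        lam_max = lambda_max_value(design.Z, design.y, l1_w)
        for lam in (lam_max, 1.5 * lam_max):
            sol = solve_weighted_enet(
                design.Z, design.y, l1_w, l2_w, lambda1=lam, lambda2=0.0
            )
            np.testing.assert_array_equal(sol.coef, np.zeros(design.Z.shape[1]))

    @pytest.mark.parametrize("seed", range(20))
    def test_objective_matches_general_minimizer(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = int(rng.integers(2, 11))
        n_G = int(rng.integers(5, 26))
        n_C = int(rng.integers(5, 26))
        pair, _, _ = random_pair(seed, n_G=n_G, n_C=n_C, p=p)
        design = build_stacked_design(pair)
        pen = PenaltySpec(float(rng.uniform(0.05, 1.0)), float(rng.uniform(0.0, 0.5)))
        l1_w, l2_w = design.weight_vectors(pen)
        e1, e2 = pen.lambda1 * l1_w, pen.lambda2 * l2_w
        sol = solve_weighted_enet(
            design.Z, design.y, l1_w, l2_w,
            lambda1=pen.lambda1, lambda2=pen.lambda2, tol=1e-9,
        )
        assert sol.converged
        ours = _oracle_objective(design.Z, design.y, sol.coef, e1, e2)
        oracle = _lbfgs_oracle(design.Z, design.y, e1, e2)
        assert ours <= oracle * (1 + 1e-6) + 1e-12
        assert abs(ours - oracle) <= 1e-6 * max(abs(oracle), 1.0)
        assert kkt_violation(
            design.Z, design.y, sol.coef, l1_w, l2_w, pen.lambda1, pen.lambda2
        ) <= 1e-6

    def test_objective_monotone_across_sweeps(self):
        pair, _, _ = random_pair(7, n_G=20, n_C=20, p=8)
        design = build_stacked_design(pair)
        l1_w, l2_w = design.weight_vectors(PenaltySpec(0.0, 0.0))
        sol = solve_weighted_enet(
            design.Z, design.y, l1_w, l2_w, lambda1=0.3, lambda2=0.05,
            return_history=True,
        )
        hist = np.array(sol.history)
        assert hist.size >= 1
        assert np.all(np.diff(hist) <= 1e-10)

    def test_python_and_numba_engines_agree(self):
        pair, _, _ = random_pair(8, p=5)
        design = build_stacked_design(pair)
        l1_w, l2_w = design.weight_vectors(PenaltySpec(0.0, 0.0))
        kw = dict(lambda1=0.2, lambda2=0.1, tol=1e-10)
        a = solve_weighted_enet(design.Z, design.y, l1_w, l2_w, engine="python", **kw)
        b = solve_weighted_enet(design.Z, design.y, l1_w, l2_w, engine="auto", **kw)
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-8)

    def test_nan_input_errors(self):
        Z = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="NaN"):
            solve_weighted_enet(
                Z, np.ones(2), np.ones(1), np.ones(1), lambda1=0.1, lambda2=0.0
            )

    def test_infinite_weight_excludes_coordinate(self):
        rng = np.random.default_rng(9)
        Z = rng.standard_normal((20, 3))
        y = Z @ np.array([1.0, 2.0, 3.0])
        sol = solve_weighted_enet(
            Z, y, np.array([1.0, np.inf, 1.0]), np.ones(3),
            lambda1=0.01, lambda2=0.001,
        )
        assert sol.coef[1] == 0.0
        assert sol.coef[0] != 0.0 and sol.coef[2] != 0.0

    def test_shrinkage_path_nonincreasing_support(self):
        pair, _, _ = random_pair(10, n_G=30, n_C=30, p=8)
        design = build_stacked_design(pair)
        l1_w, l2_w = design.weight_vectors(PenaltySpec(0.0, 0.0))
        lam_max = lambda_max_value(design.Z, design.y, l1_w)
        grid = np.geomspace(lam_max, 1e-3 * lam_max, 20)
        nnz = []
        for lam in grid:
            sol = solve_weighted_enet(
                design.Z, design.y, l1_w, l2_w, lambda1=lam, lambda2=0.05
            )
            nnz.append(int(np.sum(sol.coef != 0)))
        # support grows (ties allowed) as lambda1 decreases
        assert all(b >= a for a, b in zip(nnz, nnz[1:]))


# ---------------------------------------------------------------------------
# fit_shared


class TestFitShared:
    def test_zero_penalty_matches_least_squares(self):
        # full-rank stacked system, n_G + n_C > 2p, all weights finite
        pair, _, _ = random_pair(11, n_G=12, n_C=12, p=4, noise_sd=0.3)
        design = build_stacked_design(pair)
        expected, *_ = np.linalg.lstsq(design.Z, design.y, rcond=None)
        fit = fit_shared(
            pair, 0.0, 0.0,
            options=FitOptions(pilot_lambdas=(0.1, 0.1), weight_floor=1e-10,
                               tol=1e-10, kkt_tol=1e-8),
        )
        got = np.r_[fit.beta, fit.delta]
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_huge_lambda_gives_all_zero(self, small_pair):
        fit = fit_shared(
            small_pair, 1e12, 1.0, options=FitOptions(pilot_lambdas=(0.01, 0.01))
        )
        np.testing.assert_array_equal(fit.beta, 0.0)
        np.testing.assert_array_equal(fit.delta, 0.0)

    def test_objective_value_consistent(self, small_pair):
        opts = FitOptions(pilot_lambdas=(0.05, 0.01), seed=0)
        fit = fit_shared(small_pair, 0.5, 0.05, options=opts)
        # the stored objective includes the penalties, so it is bounded
        # below by the bare loss at the same coefficients, and is finite
        direct = objective_terms(
            small_pair, PenaltySpec(0.0, 0.0), beta=fit.beta, delta=fit.delta
        )["loss"]
        assert fit.objective_value >= direct - 1e-12
        assert np.isfinite(fit.objective_value)

    def test_delta_small_when_cohorts_identical(self):
        ratios = []
        for seed in range(20):
            pair, _, _ = random_pair(
                1000 + seed, n_G=150, n_C=150, p=20,
                beta_scale=1.5, delta_zero=True, noise_sd=1.0,
            )
            fit = fit_shared(
                pair,
                options=FitOptions(seed=seed, cv_folds=5, n_lambda1=10,
                                   lambda2_values=(0.01, 0.1)),
            )
            denom = np.abs(fit.beta).sum()
            ratios.append(np.abs(fit.delta).sum() / denom if denom else np.inf)
        assert np.median(ratios) <= 0.1

    def test_empty_cohort_degenerates_with_warning(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((40, 5))
        y = X @ np.array([2.0, -1.0, 0.0, 0.0, 0.0]) + 0.1 * rng.standard_normal(40)
        pair = CohortPair(X, y, np.zeros((0, 5)), np.zeros(0))
        fit = fit_shared(
            pair, options=FitOptions(seed=0, cv_folds=5, n_lambda1=10)
        )
        np.testing.assert_array_equal(fit.delta, 0.0)
        assert any("empty" in w for w in fit.warnings)
        assert abs(fit.beta[0]) > 0.5

    def test_all_zero_pilot_returns_zero_fit_with_warning(self, small_pair):
        fit = fit_shared(
            small_pair, 1.0, 1.0, options=FitOptions(pilot_lambdas=(1e9, 1.0))
        )
        np.testing.assert_array_equal(fit.beta, 0.0)
        assert any("zero" in w for w in fit.warnings)

    def test_mismatched_lambda_arguments_error(self, small_pair):
        with pytest.raises(ValueError, match="both lambda1 and lambda2"):
            fit_shared(small_pair, 0.5, None)


# ---------------------------------------------------------------------------
# formulation transform and prediction


class TestTransform:
    def test_printed_identity_example(self):
        fit = SharedFit(
            beta=np.array([1.0, 0.0]),
            delta_G=np.array([0.5, 0.0]),
            delta_C=np.array([0.0, 0.2]),
            formulation=Formulation.F2,
        )
        out = transform_formulations(fit)
        assert out.formulation == Formulation.F1
        np.testing.assert_allclose(out.beta, [1.5, 0.0])
        np.testing.assert_allclose(out.delta, [-0.5, 0.2])

    def test_zero_offsets_identity(self):
        fit = SharedFit(
            beta=np.array([1.0, -2.0]),
            delta_G=np.zeros(2),
            delta_C=np.zeros(2),
            formulation=Formulation.F2,
        )
        out = transform_formulations(fit)
        np.testing.assert_array_equal(out.beta, fit.beta)
        np.testing.assert_array_equal(out.delta, 0.0)

    def test_prediction_invariance_random_fits(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            p = 6
            fit = SharedFit(
                beta=rng.standard_normal(p),
                delta_G=rng.standard_normal(p),
                delta_C=rng.standard_normal(p),
                formulation=Formulation.F2,
            )
            X = rng.standard_normal((9, p))
            out = transform_formulations(fit)
            for mode in ("as_G", "as_C"):
                np.testing.assert_allclose(
                    predict_shared(fit, X, mode),
                    predict_shared(out, X, mode),
                    atol=1e-12,
                )

    def test_round_trip_f1_to_f2(self):
        rng = np.random.default_rng(14)
        fit = SharedFit(
            beta=rng.standard_normal(4), delta=rng.standard_normal(4),
            formulation=Formulation.F1,
        )
        back = transform_formulations(transform_formulations(fit))
        np.testing.assert_allclose(back.beta, fit.beta, atol=1e-12)
        np.testing.assert_allclose(back.delta, fit.delta, atol=1e-12)

    def test_fitted_f2_transforms_to_f1_predictions(self):
        pair, _, _ = random_pair(15, n_G=30, n_C=30, p=5)
        fit2 = fit_shared(
            pair, 0.2, 0.05, formulation=Formulation.F2,
            options=FitOptions(pilot_lambdas=(0.1, 0.05), seed=0),
        )
        fit1 = transform_formulations(fit2)
        for mode, X in (("as_G", pair.X_G), ("as_C", pair.X_C)):
            np.testing.assert_allclose(
                predict_shared(fit2, X, mode),
                predict_shared(fit1, X, mode),
                atol=1e-8,
            )


class TestPredict:
    def test_zero_matrix_gives_zero(self):
        fit = SharedFit(beta=np.ones(3), delta=np.ones(3))
        np.testing.assert_array_equal(
            predict_shared(fit, np.zeros((4, 3)), "as_G"), np.zeros(4)
        )

    def test_zero_delta_modes_agree(self):
        rng = np.random.default_rng(16)
        fit = SharedFit(beta=rng.standard_normal(3), delta=np.zeros(3))
        X = rng.standard_normal((5, 3))
        np.testing.assert_array_equal(
            predict_shared(fit, X, "as_G"), predict_shared(fit, X, "as_C")
        )

    def test_matches_direct_product(self):
        rng = np.random.default_rng(17)
        beta = rng.standard_normal(4)
        delta = rng.standard_normal(4)
        fit = SharedFit(beta=beta, delta=delta)
        X = rng.standard_normal((6, 4))
        np.testing.assert_allclose(
            predict_shared(fit, X, "as_C"), X @ (beta + delta), atol=1e-12
        )

    def test_column_mismatch_errors(self):
        fit = SharedFit(beta=np.ones(3), delta=np.zeros(3))
        with pytest.raises(ValueError, match="columns"):
            predict_shared(fit, np.ones((2, 4)), "as_G")

    def test_unknown_mode_errors(self):
        fit = SharedFit(beta=np.ones(2), delta=np.zeros(2))
        with pytest.raises(ValueError, match="mode"):
            predict_shared(fit, np.ones((1, 2)), "as_B")
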