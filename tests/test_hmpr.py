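"""Polynomial basis, truncated-SVD least squares, pruning, selection,
gradients, serialization."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from affectscr.exceptions import EmptyInputError, SchemaError
from affectscr.hmpr import (
    HMPR,
    FitConfig,
    PolynomialModel,
    build_design,
    fit_hmpm,
    gradient,
    gradient_field,
    load_model,
    monomial_exponents,
    predict,
    prune_insignificant,
    save_model,
    select_order,
    truncated_ls,
)


def _brute_force_count(m, p):
    from itertools import product
    return sum(1 for e in product(range(p + 1), repeat=m) if sum(e) <= p)


class TestMonomialExponents:
    def test_linear_basis_in_two_variables(self):
        assert monomial_exponents(2, 1) == [(0, 0), (1, 0), (0, 1)]

    def test_order_eight_two_variables_has_45_terms(self):
        assert len(monomial_exponents(2, 8)) == 45 == comb(10, 2)

    def test_intercept_only_for_order_zero(self):
        assert monomial_exponents(3, 0) == [(0, 0, 0)]

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(m=st.integers(1, 4), p=st.integers(0, 10))
    def test_count_matches_brute_force_enumeration(self, m, p):
        exps = monomial_exponents(m, p)
        assert len(exps) == _brute_force_count(m, p) == comb(m + p, m)
        assert len(set(exps)) == len(exps)
        assert all(sum(e) <= p for e in exps)


class TestBuildDesign:
    def test_single_monomial_hand_value(self):
        np.testing.assert_array_equal(
            build_design([[2.0, 3.0]], [(1, 1)]), [[6.0]])

    def test_unit_inputs_give_all_ones_row(self):
        A = build_design([[1.0, 1.0]], monomial_exponents(2, 4))
        np.testing.assert_array_equal(A, np.ones((1, 15)))

    def test_matches_elementwise_power_product_oracle(self, rng):
        X = rng.normal(size=(5, 2))
        exps = monomial_exponents(2, 3)
        A = build_design(X, exps)
        for i in range(5):
            for k, e in enumerate(exps):
                expected = X[i, 0] ** e[0] * X[i, 1] ** e[1]
                assert A[i, k] == pytest.approx(expected, abs=1e-12)


class TestTruncatedLS:
    def test_identity_design_returns_response(self, rng):
        y = rng.normal(size=6)
        coef, _, _, rank = truncated_ls(np.eye(6), y)
        np.testing.assert_allclose(coef, y, atol=1e-12)
        assert rank == 6

    def test_rank_deficient_design_matches_pseudoinverse_oracle(self, rng):
        base = rng.normal(size=(20, 3))
        A = np.column_stack([base, base[:, 1]])  # duplicated column
        y = rng.normal(size=20)
        coef, _, _, rank = truncated_ls(A, y, singular_criterion=1e-8)
        oracle = np.linalg.pinv(A, rcond=1e-8) @ y
        np.testing.assert_allclose(coef, oracle, atol=1e-8)
        assert rank == 3

    def test_well_conditioned_matches_normal_equations(self, rng):
        A = rng.normal(size=(50, 6))
        y = rng.normal(size=50)
        coef, _, _, _ = truncated_ls(A, y)
        oracle = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(coef, oracle, atol=1e-8)

    def test_standard_errors_match_classical_ols_formula(self, rng):
        A = rng.normal(size=(40, 4))
        y = A @ np.array([1.0, -2.0, 0.5, 3.0]) + rng.normal(0, 0.1, 40)
        coef, se, p, rank = truncated_ls(A, y)
        resid = y - A @ coef
        sigma2 = resid @ resid / (40 - 4)
        cov = sigma2 * np.linalg.inv(A.T @ A)
        np.testing.assert_allclose(se, np.sqrt(np.diag(cov)), rtol=1e-8)

    def test_saturated_fit_flags_pvalues_undefined(self, rng):
        A = rng.normal(size=(3, 3))
        _, se, p, _ = truncated_ls(A, rng.normal(size=3))
        assert np.all(np.isnan(p)) and np.all(np.isnan(se))

    def test_zero_rows_rejected(self):
        with pytest.raises(EmptyInputError):
            truncated_ls(np.empty((0, 2)), np.empty(0))


class TestPruneAndFit:
    def test_sparse_truth_prunes_to_true_support(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-2, 2, size=(200, 2))
        y = 3.0 + 2.0 * X[:, 0] + rng.normal(0, 0.01, 200)
        model = fit_hmpm(X, y, order=2)
        assert set(model.exponents) == {(0, 0), (1, 0)}
        np.testing.assert_allclose(model.coefficients, [3.0, 2.0], atol=0.01)

    def test_fully_significant_model_unchanged(self, rng):
        X = rng.uniform(1, 2, size=(100, 1))
        y = 1.0 + 2.0 * X[:, 0] + rng.normal(0, 0.001, 100)
        unpruned = fit_hmpm(X, y, order=1, prune=False)
        pruned = prune_insignificant(unpruned, X, y, FitConfig())
        assert pruned.exponents == unpruned.exponents

    def test_alpha_one_is_a_noop(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        cfg = FitConfig(significance_level=1 - 1e-12)
        unpruned = fit_hmpm(X, y, order=2, config=cfg, prune=False)
        pruned = prune_insignificant(unpruned, X, y, cfg)
        assert pruned.exponents == unpruned.exponents

    def test_intercept_survives_pure_noise(self, rng):
        X = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        model = fit_hmpm(X, y, order=2)
        assert (0, 0) in model.exponents

    def test_exact_quadratic_recovered_without_noise(self):
        X = np.linspace(-2, 2, 30)[:, None]
        y = 1.0 - 3.0 * X[:, 0] + 0.5 * X[:, 0] ** 2
        model = fit_hmpm(X, y, order=2, prune=False)
        np.testing.assert_allclose(model.coefficients, [1.0, -3.0, 0.5],
                                   atol=1e-8)

    def test_first_order_fit_is_multivariate_linear_regression(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        model = fit_hmpm(X, y, order=1, prune=False)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(model.coefficients, ols.params, atol=1e-10)
        np.testing.assert_allclose(model.coef_se, ols.bse, atol=1e-10)

    def test_noisy_cubic_coefficient_recovery(self):
        rng = np.random.default_rng(11)
        exps = monomial_exponents(2, 3)
        truth = rng.uniform(0.5, 2.0, len(exps)) * rng.choice([-1, 1],
                                                              len(exps))
        X = rng.uniform(-1.5, 1.5, size=(84, 2))
        y = build_design(X, exps) @ truth + rng.normal(0, 0.05, 84)
        model = fit_hmpm(X, y, order=3)
        fitted = dict(zip(model.exponents, model.coefficients))
        for e, c in zip(exps, truth):
            assert fitted.get(e, 0.0) == pytest.approx(c, rel=0.05)

    def test_training_mse_nests_across_orders_before_pruning(self, rng):
        X = rng.uniform(-1, 1, size=(40, 2))
        y = np.sin(X[:, 0]) + X[:, 1] ** 2 + rng.normal(0, 0.05, 40)
        prev = np.inf
        for p in range(0, 6):
            model = fit_hmpm(X, y, order=p, prune=False)
            m = float(np.mean((y - predict(model, X)) ** 2))
            assert m <= prev + 1e-12
            prev = m

    def test_residuals_orthogonal_to_retained_columns(self, rng):
        X = rng.uniform(-1, 1, size=(60, 2))
        y = rng.normal(size=60)
        model = fit_hmpm(X, y, order=3, prune=False)
        A = build_design(X, model.exponents)
        resid = y - A @ model.coefficients
        assert np.max(np.abs(A.T @ resid)) < 1e-6

    def test_coefficient_rmse_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        exps = monomial_exponents(2, 2)
        truth = np.array([1.0, -2.0, 1.5, 0.8, -1.2, 0.6])
        rmses = []
        for n in (50, 200, 1000):
            X = rng.uniform(-1, 1, size=(n, 2))
            y = build_design(X, exps) @ truth + rng.normal(0, 0.3, n)
            model = fit_hmpm(X, y, order=2, prune=False)
            rmses.append(float(np.sqrt(np.mean(
                (model.coefficients - truth) ** 2))))
        assert rmses[0] > rmses[1] > rmses[2]


class TestPredictAndGradient:
    def test_intercept_only_model_is_constant(self):
        model = PolynomialModel(2, 0, ((0, 0),), [5.0], [0.0], [0.0])
        np.testing.assert_array_equal(predict(model, [[1.0, 9.0], [0, 0]]),
                                      [5.0, 5.0])

    def test_hand_evaluated_linear_model(self):
        model = PolynomialModel(2, 1, ((0, 0), (1, 0)), [1.0, 2.0],
                                [0, 0], [0, 0])
        assert predict(model, [[3.0, 7.0]])[0] == 7.0

    def test_dimension_mismatch_raises(self):
        model = PolynomialModel(2, 1, ((0, 0),), [1.0], [0], [0])
        with pytest.raises(SchemaError):
            predict(model, [[1.0, 2.0, 3.0]])
        with pytest.raises(SchemaError):
            gradient(model, [1.0])

    def test_constant_model_has_zero_gradient(self):
        model = PolynomialModel(2, 0, ((0, 0),), [4.2], [0], [0])
        np.testing.assert_array_equal(gradient(model, [3.0, -1.0]), [0.0, 0.0])

    def test_linear_model_gradient_is_its_slope_everywhere(self):
        model = PolynomialModel(2, 1, ((1, 0), (0, 1)), [1.0, 2.0],
                                [0, 0], [0, 0])
        for pt in ([0.0, 0.0], [5.0, -3.0]):
            np.testing.assert_array_equal(gradient(model, pt), [1.0, 2.0])

    def test_gradient_matches_central_finite_differences(self):
        rng = np.random.default_rng(17)
        exps = monomial_exponents(2, 5)
        model = PolynomialModel(2, 5, tuple(exps),
                                rng.normal(size=len(exps)),
                                np.zeros(len(exps)), np.zeros(len(exps)))
        h = 1e-6
        for pt in rng.uniform(-1.5, 1.5, size=(20, 2)):
            g = gradient(model, pt)
            fd = np.empty(2)
            for v in range(2):
                e = np.zeros(2)
                e[v] = h
                fd[v] = (predict(model, [pt + e])[0]
                         - predict(model, [pt - e])[0]) / (2 * h)
            np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-6)

    def test_gradient_field_delegates_to_gradient(self):
        model = PolynomialModel(2, 1, ((1, 0), (0, 1)), [1.0, 2.0],
                                [0, 0], [0, 0])
        pts, vecs = gradient_field(model, [(0, 1), (0, 1)], num=3)
        assert pts.shape == (9, 2) and vecs.shape == (9, 2)
        np.testing.assert_array_equal(vecs, np.tile([1.0, 2.0], (9, 1)))
        with pytest.raises(EmptyInputError):
            gradient_field(model, [(0, 1), (0, 1)], num=0)


class TestSelectOrder:
    def test_single_candidate_is_returned(self, rng):
        X = rng.uniform(-1, 1, size=(30, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        best, reports = select_order(X, y, X, y, [2])
        assert best.order == 2 and list(reports) == [2]

    def test_generating_order_selected_on_heldout_noiseless_grid(self):
        rng = np.random.default_rng(3)
        exps = monomial_exponents(2, 3)
        truth = rng.uniform(0.5, 1.5, len(exps))
        X = rng.uniform(-1.5, 1.5, size=(120, 2))
        y = build_design(X, exps) @ truth + rng.normal(0, 0.05, 120)
        grid = np.linspace(-1.5, 1.5, 12)
        GX = np.array([[a, b] for a in grid for b in grid])
        gy = build_design(GX, exps) @ truth
        best, _ = select_order(X, y, GX, gy, range(1, 7))
        assert best.order == 3

    def test_ties_break_toward_lower_order(self):
        # noiseless linear data: every order interpolates; lowest must win
        rng = np.random.default_rng(4)
        X = rng.uniform(0.5, 2.0, size=(40, 2))
        y = 1.0 + 2.0 * X[:, 0] - X[:, 1]
        best, _ = select_order(X, y, X, y, range(1, 4))
        assert best.order == 1


class TestSerialization:
    def test_round_trip_preserves_predictions_bit_exactly(self, rng, tmp_path):
        X = rng.uniform(-1, 1, size=(50, 2))
        y = rng.normal(size=50)
        model = fit_hmpm(X, y, order=3, target_label="valence",
                         var_names=("gain", "decay_time_constant"))
        path = tmp_path / "model.csv"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.exponents == model.exponents
        np.testing.assert_array_equal(loaded.coefficients, model.coefficients)
        np.testing.assert_array_equal(predict(loaded, X), predict(model, X))
        assert loaded.target_label == "valence"
        assert loaded.var_names == ("gain", "decay_time_constant")

    def test_duplicate_exponent_tuples_rejected(self, tmp_path):
        with pytest.raises(SchemaError):
            PolynomialModel(2, 1, ((1, 0), (1, 0)), [1.0, 2.0],
                            [0, 0], [0, 0])

    def test_degree_above_declared_order_rejected(self):
        with pytest.raises(SchemaError):
            PolynomialModel(2, 1, ((2, 0),), [1.0], [0], [0])


class TestModelResultsSurface:
    def test_fit_summary_and_dataframe_constructor(self, default_table):
        res = HMPR.from_dataframe(default_table, "arousal",
                                  ["gain", "decay_time_constant"],
                                  order=2).fit()
        text = res.summary()
        assert "arousal" in text and "gain" in text
        assert res.nobs == len(default_table)
        assert len(res.params) == len(res.exponents)
        assert res.predict(default_table[
            ["gain", "decay_time_constant"]].to_numpy()).shape == (24,)

    def test_column_equilibration_changes_only_conditioning(self, rng):
        X = rng.uniform(0.5, 2.0, size=(60, 2))
        y = 1.0 + X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 0.01, 60)
        plain = fit_hmpm(X, y, order=2, prune=False)
        equil = fit_hmpm(X, y, order=2, prune=False,
                         config=FitConfig(standardize=True))
        np.testing.assert_allclose(equil.coefficients, plain.coefficients,
                                   rtol=1e-6, atol=1e-8)
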