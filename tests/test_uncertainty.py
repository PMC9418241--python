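"""Epistemic uncertainty, filtering threshold, and the OLS correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epibayes.network import TrainConfig, train_bnn
from epibayes.data import stratified_split
from epibayes.uncertainty import (
    MCPredictions,
    UncertaintyEstimate,
    apply_correction,
    epistemic_matrix,
    epistemic_scalar,
    filter_predictions,
    fit_correction,
    inv_logit,
    logit,
    mc_predict,
    training_uncertainty_threshold,
)


def mcpred_from(draws):
    draws = np.asarray(draws, dtype=float)
    mean = draws.mean(axis=0)
    return MCPredictions(draws, mean, np.argmax(mean, axis=1))


def random_mcpred(rng, T, N, C):
    draws = rng.dirichlet(np.full(C, 0.5), size=(T, N))
    return mcpred_from(draws)


@pytest.fixture(scope="module")
def model_and_data(small_cohort):
    _, ds = small_cohort
    split = stratified_split(ds, 0.8, seed=1)
    model = train_bnn(
        split.train, hidden_sizes=(16, 8), config=TrainConfig(epochs=30, seed=2)
    )
    return model, split.test.matrix.values


class TestMcPredict:
    def test_tensor_shape(self, model_and_data):
        model, X = model_and_data
        mcp = mc_predict(model, X, T=7, seed=3)
        assert mcp.draws.shape == (7, X.shape[0], 3)
        np.testing.assert_allclose(mcp.draws.sum(axis=2), 1.0, atol=1e-9)
        np.testing.assert_allclose(mcp.mean_probs, mcp.draws.mean(axis=0), atol=1e-12)

    def test_deterministic_given_seed(self, model_and_data):
        model, X = model_and_data
        a = mc_predict(model, X, T=5, seed=9)
        b = mc_predict(model, X, T=5, seed=9)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_default_draw_count_is_500(self, model_and_data):
        model, X = model_and_data
        assert mc_predict(model, X[:2], seed=0).T == 500

    def test_feature_mismatch_rejected(self, model_and_data):
        model, X = model_and_data
        with pytest.raises(ValueError, match="feature"):
            mc_predict(model, X[:, :5], T=2, seed=0)


class TestEpistemicMatrix:
    def test_single_draw_gives_zero_matrix(self):
        mcp = mcpred_from([[[0.2, 0.8]]])
        np.testing.assert_array_equal(epistemic_matrix(mcp, 0), np.zeros((2, 2)))

    def test_hand_computed_two_draw_case(self):
        mcp = mcpred_from([[[0.4, 0.6]], [[0.6, 0.4]]])
        np.testing.assert_allclose(
            epistemic_matrix(mcp, 0), [[0.01, -0.01], [-0.01, 0.01]], atol=1e-15
        )

    def test_positive_semidefinite(self, rng):
        mcp = random_mcpred(rng, T=20, N=4, C=6)
        for i in range(4):
            evals = np.linalg.eigvalsh(epistemic_matrix(mcp, i))
            assert evals.min() >= -1e-12

    def test_bad_sample_index_rejected(self, rng):
        with pytest.raises(IndexError):
            epistemic_matrix(random_mcpred(rng, 3, 2, 2), 5)


class TestEpistemicScalar:
    def test_constant_draws_give_zero(self):
        mcp = mcpred_from(np.tile([[0.1, 0.9]], (6, 3, 1)))
        assert (epistemic_scalar(mcp).xi == 0).all()

    def test_hand_computed_two_draw_value(self):
        mcp = mcpred_from([[[0.4, 0.6]], [[0.6, 0.4]]])
        est = epistemic_scalar(mcp)
        assert est.xi[0] == pytest.approx(0.01)

    def test_scalar_equals_matrix_diagonal_at_predicted_class(self, rng):
        mcp = random_mcpred(rng, T=15, N=6, C=4)
        est = epistemic_scalar(mcp)
        for i in range(6):
            mat = epistemic_matrix(mcp, i)
            np.testing.assert_allclose(est.class_variances[i], np.diag(mat), atol=1e-14)
            assert est.xi[i] == pytest.approx(mat[est.predicted_class[i],
                                                  est.predicted_class[i]])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), T=st.integers(1, 50), C=st.integers(2, 10))
    def test_matches_brute_force_variance_and_stays_bounded(self, seed, T, C):
        rng = np.random.default_rng(seed)
        mcp = random_mcpred(rng, T=T, N=3, C=C)
        est = epistemic_scalar(mcp)
        for i in range(3):
            c = mcp.predicted_class[i]
            brute = np.mean((mcp.draws[:, i, c] - mcp.draws[:, i, c].mean()) ** 2)
            assert abs(est.xi[i] - brute) < 1e-12
        assert (est.xi >= 0).all() and (est.xi <= 0.25).all()


class TestThresholdAndFilter:
    def test_threshold_is_mean_over_correct_samples(self):
        est = UncertaintyEstimate(
            predicted_class=np.array([0, 1, 0]),
            xi=np.array([0.01, 0.03, 0.5]),
            class_variances=np.zeros((3, 2)),
        )
        y_true = np.array([0, 1, 1])  # third sample is wrong
        assert training_uncertainty_threshold(est, y_true) == pytest.approx(0.02)

    def test_single_correct_sample(self):
        est = UncertaintyEstimate(np.array([1, 0]), np.array([0.07, 0.2]),
                                  np.zeros((2, 2)))
        assert training_uncertainty_threshold(est, np.array([1, 1])) == pytest.approx(0.07)

    def test_no_correct_predictions_rejected(self):
        est = UncertaintyEstimate(np.array([0]), np.array([0.1]), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            training_uncertainty_threshold(est, np.array([1]))

    def test_per_class_variant(self):
        est = UncertaintyEstimate(np.array([0, 0, 1]), np.array([0.01, 0.03, 0.1]),
                                  np.zeros((3, 2)))
        out = training_uncertainty_threshold(est, np.array([0, 0, 0]), per_class=True)
        assert out[0] == pytest.approx(0.02) and np.isnan(out[1])

    def test_filter_hand_case(self):
        est = UncertaintyEstimate(np.array([0, 0]), np.array([0.01, 0.05]),
                                  np.zeros((2, 2)))
        result = filter_predictions(est, 0.02)
        np.testing.assert_array_equal(result.retained, [True, False])
        assert result.retained_fraction == pytest.approx(0.5)

    def test_boundary_value_is_dropped(self):
        est = UncertaintyEstimate(np.array([0]), np.array([0.02]), np.zeros((1, 2)))
        result = filter_predictions(est, 0.02)
        assert not result.retained[0] and result.empty

    def test_all_below_threshold_retains_everything(self):
        est = UncertaintyEstimate(np.array([0, 1]), np.array([0.001, 0.002]),
                                  np.zeros((2, 2)))
        assert filter_predictions(est, 0.1).retained_fraction == 1.0


class TestLogit:
    def test_symmetry_point(self):
        assert logit(0.5) == 0.0

    def test_round_trip(self):
        assert inv_logit(logit(0.3)) == pytest.approx(0.3, abs=1e-9)

    def test_ln_nine(self):
        assert logit(0.9) == pytest.approx(np.log(9.0), abs=1e-9)
        assert logit(0.9) == pytest.approx(2.197225, abs=1e-6)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            logit(np.nan)
        with pytest.raises(ValueError):
            inv_logit(np.inf)


class TestFitCorrection:
    def test_recovers_noiseless_line_exactly(self):
        xi = np.linspace(0.0004, 0.04, 30)
        probs = inv_logit(2.0 - 3.0 * np.sqrt(xi))[:, None]
        probs = np.hstack([probs, 1 - probs])
        est = UncertaintyEstimate(np.zeros(30, dtype=int), xi,
                                  np.column_stack([xi, xi]))
        model = fit_correction(probs, est)
        assert model.alpha[0] == pytest.approx(2.0, abs=1e-9)
        assert model.beta[0] == pytest.approx(-3.0, abs=1e-9)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        xi = rng.uniform(0.001, 0.2, size=40)
        probs = np.clip(rng.uniform(0.2, 0.95, size=40), None, None)[:, None]
        probs = np.hstack([probs, 1 - probs])
        est = UncertaintyEstimate(np.zeros(40, dtype=int), xi,
                                  np.column_stack([xi, xi]))
        model = fit_correction(probs, est)
        X = sm.add_constant(np.sqrt(xi))
        ref = sm.OLS(logit(probs[:, 0]), X).fit()
        assert model.alpha[0] == pytest.approx(ref.params[0], abs=1e-10)
        assert model.beta[0] == pytest.approx(ref.params[1], abs=1e-10)

    def test_null_slope_within_confidence_band(self):
        from scipy.stats import t as t_dist

        rng = np.random.default_rng(77)
        n = 200
        xi = rng.uniform(0.001, 0.09, size=n)
        z = 1.0 + rng.normal(0, 0.3, size=n)  # response independent of xi
        probs = np.column_stack([inv_logit(z), 1 - inv_logit(z)])
        est = UncertaintyEstimate(np.zeros(n, dtype=int), xi,
                                  np.column_stack([xi, xi]))
        model = fit_correction(probs, est)
        x = np.sqrt(xi)
        sxx = np.sum((x - x.mean()) ** 2)
        half_width = t_dist.ppf(0.975, n - 2) * np.sqrt(model.sigma2[0] / sxx)
        assert abs(model.beta[0]) < half_width

    def test_sparse_class_flagged_with_zero_slope(self):
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.7, 0.3], [0.6, 0.4]])
        est = UncertaintyEstimate(np.array([0, 0, 0, 1]),
                                  np.array([0.01, 0.02, 0.03, 0.04]),
                                  np.tile([[0.01, 0.01]], (4, 1)))
        model = fit_correction(probs, est)
        assert model.flagged[1] and model.beta[1] == 0.0
        assert model.n_points[1] == 1


class TestApplyCorrection:
    def make_est(self, probs, var):
        probs = np.asarray(probs, dtype=float)
        var = np.asarray(var, dtype=float)
        pred = np.argmax(probs, axis=1)
        return UncertaintyEstimate(pred, var[np.arange(len(pred)), pred], var)

    def test_zero_slopes_leave_probabilities_unchanged(self):
        probs = np.array([[0.7, 0.3], [0.2, 0.8]])
        est = self.make_est(probs, np.full((2, 2), 0.01))
        from epibayes.uncertainty import CorrectionModel

        model = CorrectionModel(np.zeros(2), np.zeros(2), np.zeros(2),
                                np.array([1, 1]), np.array([True, True]))
        for scope in ("predicted", "all_classes"):
            out = apply_correction(probs, est, model, scope=scope)
            np.testing.assert_allclose(out.probs, probs, atol=1e-9)
            np.testing.assert_array_equal(out.corrected_class, [0, 1])

    def test_zero_uncertainty_sample_is_fixed_point_of_canonical(self):
        probs = np.array([[0.7, 0.3]])
        est = self.make_est(probs, np.zeros((1, 2)))
        from epibayes.uncertainty import CorrectionModel

        model = CorrectionModel(np.array([1.0, 1.0]), np.array([-3.0, -3.0]),
                                np.zeros(2), np.array([10, 10]),
                                np.array([False, False]))
        out = apply_correction(probs, est, model, variant="canonical",
                               scope="all_classes")
        np.testing.assert_allclose(out.probs, probs, atol=1e-6)

    def test_hand_computed_canonical_value(self):
        # E[p] = 0.6, xi = 0.04, beta = 1 -> f^-1(ln(1.5) - 0.2) ~ 0.55119
        probs = np.array([[0.6, 0.4]])
        est = self.make_est(probs, np.array([[0.04, 0.0]]))
        from epibayes.uncertainty import CorrectionModel

        model = CorrectionModel(np.zeros(2), np.array([1.0, 0.0]), np.zeros(2),
                                np.array([10, 10]), np.array([False, False]))
        out = apply_correction(probs, est, model, variant="canonical")
        assert out.probs[0, 0] == pytest.approx(0.55119, abs=1e-5)

    def test_literal_variant_applies_printed_formula(self):
        probs = np.array([[0.6, 0.4]])
        est = self.make_est(probs, np.array([[0.04, 0.0]]))
        from epibayes.uncertainty import CorrectionModel

        model = CorrectionModel(np.zeros(2), np.array([1.0, 0.0]), np.zeros(2),
                                np.array([10, 10]), np.array([False, False]))
        out = apply_correction(probs, est, model, variant="literal")
        assert out.probs[0, 0] == pytest.approx(inv_logit(0.6 - 0.04), abs=1e-9)

    def test_predicted_scope_only_touches_the_call(self):
        probs = np.array([[0.6, 0.3, 0.1]])
        var = np.array([[0.02, 0.01, 0.005]])
        est = self.make_est(probs, var)
        from epibayes.uncertainty import CorrectionModel

        model = CorrectionModel(np.zeros(3), np.array([-2.0, -2.0, -2.0]),
                                np.zeros(3), np.array([9, 9, 9]),
                                np.array([False] * 3))
        out = apply_correction(probs, est, model, scope="predicted")
        assert out.probs[0, 1] == probs[0, 1] and out.probs[0, 2] == probs[0, 2]
        assert out.probs[0, 0] != probs[0, 0]

    def test_unknown_variant_or_scope_rejected(self):
        probs = np.array([[0.6, 0.4]])
        est = self.make_est(probs, np.zeros((1, 2)))
        from epibayes.uncertainty import CorrectionModel

        model = CorrectionModel(np.zeros(2), np.zeros(2), np.zeros(2),
                                np.array([3, 3]), np.array([False, False]))
        with pytest.raises(ValueError):
            apply_correction(probs, est, model, variant="bogus")
        with pytest.raises(ValueError):
            apply_correction(probs, est, model, scope="bogus")
        with pytest.raises(ValueError):
            apply_correction(np.array([[0.2, 0.3, 0.5]]), est, model)
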