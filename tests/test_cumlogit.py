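import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from adjiv.cumlogit import (
    CollinearityWarning,
    LogisticRegressionMLE,
    ProportionalOddsRegressor,
    fit_logistic,
    fit_proportional_odds,
    nagelkerke_r2,
    pseudo_r2,
)
from helpers import brute_force_po, grouped_to_rows, numeric_hessian, po_negloglik


def _simulate_po(rng, n, beta, alpha=(-1.0, 0.0, 1.0)):
    p = len(beta)
    X = rng.normal(size=(n, p))
    F = expit(np.asarray(alpha)[None, :] + (X @ np.asarray(beta))[:, None])
    y = 1 + (rng.random(n)[:, None] > F).sum(1)
    return X, y


class TestProportionalOdds:
    def test_matches_brute_force_on_grouped_table(self):
        """Binary predictor, 4 outcome levels, fixed cell counts."""
        X, y = grouped_to_rows([0.0, 1.0], [[30, 20, 25, 25], [12, 18, 30, 40]])
        fit = fit_proportional_odds(X, y)
        alpha_bf, beta_bf, ll_bf = brute_force_po(X, y)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(beta_bf[0], abs=1e-6)
        assert np.allclose(fit.cutpoints, alpha_bf, atol=1e-6)
        assert fit.loglik == pytest.approx(ll_bf, abs=1e-8)

    def test_binary_outcome_reduces_to_logistic(self, rng):
        X = rng.normal(size=(400, 2))
        y = rng.binomial(1, expit(0.4 + X @ np.array([0.8, -0.5])))
        po = fit_proportional_odds(X, y + 1)  # categories {1, 2}
        lo = fit_logistic(X, 1 - y)  # P(Y<=1) = P(y == 0)
        assert np.allclose(po.coef, lo.coef, atol=1e-8)
        assert po.cutpoints[0] == pytest.approx(lo.intercept, abs=1e-8)
        assert po.loglik == pytest.approx(lo.loglik, abs=1e-8)

    def test_null_generated_data_estimates_near_zero(self, rng):
        X, y = _simulate_po(rng, 50_000, beta=[0.0, 0.0])
        fit = fit_proportional_odds(X, y)
        assert fit.converged
        assert np.all(np.abs(fit.coef) < 4 * fit.se)

    def test_cutpoints_strictly_increasing(self, rng):
        X, y = _simulate_po(rng, 2000, beta=[0.7])
        fit = fit_proportional_odds(X, y)
        assert np.all(np.diff(fit.cutpoints) > 0)

    def test_se_matches_finite_difference_hessian(self, rng):
        X, y = _simulate_po(rng, 1500, beta=[0.5, -0.3])
        fit = fit_proportional_odds(X, y)
        theta = np.concatenate([fit.cutpoints, fit.coef])
        y01 = np.unique(y, return_inverse=True)[1]
        H = numeric_hessian(lambda th: -po_negloglik(th, X, y01, 4), theta)
        se_fd = np.sqrt(np.diag(np.linalg.inv(-H)))
        se_fit = np.concatenate([fit.se_cutpoints, fit.se])
        np.testing.assert_allclose(se_fit, se_fd, rtol=1e-4)

    def test_equivariance_under_column_rescaling(self, rng):
        X, y = _simulate_po(rng, 3000, beta=[0.6, -0.4])
        f1 = fit_proportional_odds(X, y)
        X2 = X.copy()
        X2[:, 0] *= 10.0
        f2 = fit_proportional_odds(X2, y)
        assert f2.coef[0] == pytest.approx(f1.coef[0] / 10.0, rel=1e-6)
        assert f2.se[0] == pytest.approx(f1.se[0] / 10.0, rel=1e-6)
        z1, z2 = f1.coef / f1.se, f2.coef / f2.se
        np.testing.assert_allclose(z1, z2, rtol=1e-6)

    def test_statsmodels_crosscheck(self, rng):
        """Independent established implementation agrees to 1e-5."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        checked = 0
        for _ in range(10):
            n = int(rng.integers(150, 400))
            p = int(rng.integers(1, 4))
            beta = rng.normal(scale=0.6, size=p)
            X, y = _simulate_po(rng, n, beta)
            if len(np.unique(y)) < 4:
                continue
            fit = fit_proportional_odds(X, y)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm_fit = OrderedModel(y, X, distr="logit").fit(
                    method="bfgs", disp=False, gtol=1e-9)
            # statsmodels models P(Y<=k) = F(cut_k - x beta)
            np.testing.assert_allclose(fit.coef, -sm_fit.params[:p], atol=1e-5)
            assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-6)
            checked += 1
        assert checked >= 5

    def test_single_category_rejected(self):
        with pytest.raises(Exception, match="categories"):
            fit_proportional_odds(np.zeros((10, 1)), np.ones(10))

    @settings(max_examples=12, deadline=None, derandomize=True,
              suppress_health_check=[HealthCheck.too_slow])
    @given(seed=st.integers(0, 10_000), n=st.integers(120, 400),
           b=st.floats(-1.2, 1.2, allow_nan=False))
    def test_fit_invariants_property(self, seed, n, b):
        """Converged fits: ll >= null ll, monotone cuts, positive SEs."""
        rng = np.random.default_rng(seed)
        X, y = _simulate_po(rng, n, beta=[b])
        if len(np.unique(y)) < 2:
            return
        fit = fit_proportional_odds(X, y)
        assert fit.loglik >= fit.loglik_null - 1e-8
        assert np.all(np.diff(fit.cutpoints) > 0)
        if fit.converged:
            assert np.all(fit.se[np.isfinite(fit.se)] > 0)


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_logistic(np.zeros((100, 0)), y)
        assert fit.intercept == pytest.approx(logit(0.3), abs=1e-10)

    def test_two_by_two_table_log_odds_ratio(self):
        # cells: x=0: 40 / 60, x=1: 55 / 45
        x = np.array([0.0] * 100 + [1.0] * 100)[:, None]
        y = np.array([1] * 40 + [0] * 60 + [1] * 55 + [0] * 45)
        fit = fit_logistic(x, y)
        lor = np.log((55 / 45) / (40 / 60))
        assert fit.coef[0] == pytest.approx(lor, abs=1e-8)
        assert fit.intercept == pytest.approx(logit(0.4), abs=1e-8)

    def test_complete_separation_flagged(self):
        x = np.linspace(-1, 1, 60)[:, None]
        y = (x[:, 0] > 0).astype(int)
        fit = fit_logistic(x, y)
        assert not fit.converged

    def test_constant_outcome_rejected(self):
        with pytest.raises(Exception, match="constant"):
            fit_logistic(np.random.default_rng(0).normal(size=(20, 1)), np.ones(20))


class TestCollinearity:
    def test_duplicate_column_dropped_and_named(self, rng):
        X, y = _simulate_po(rng, 500, beta=[0.5])
        X2 = np.column_stack([X, X])
        with pytest.warns(CollinearityWarning, match="dup"):
            fit = fit_proportional_odds(X2, y, feature_names=["orig", "dup"])
        assert fit.dropped == ["dup"]
        assert np.isnan(fit.coef[1]) and np.isfinite(fit.coef[0])

    def test_constant_column_absorbed_by_cutpoints(self, rng):
        X, y = _simulate_po(rng, 500, beta=[0.5])
        X2 = np.column_stack([X, np.full(500, 3.0)])
        with pytest.warns(CollinearityWarning):
            fit = fit_proportional_odds(X2, y, feature_names=["x", "const"])
        assert fit.dropped == ["const"]


class TestPseudoR2:
    def test_zero_when_model_equals_null(self, rng):
        y = (rng.random(500) < 0.4).astype(int)
        fit = fit_logistic(np.zeros((500, 0)), y)
        assert nagelkerke_r2(fit) == pytest.approx(0.0, abs=1e-10)

    def test_hand_evaluation_on_2x2(self):
        x = np.array([0.0] * 50 + [1.0] * 50)[:, None]
        y = np.array([1] * 10 + [0] * 40 + [1] * 30 + [0] * 20)
        fit = fit_logistic(x, y)
        n = 100
        cs = 1 - np.exp(2 * (fit.loglik_null - fit.loglik) / n)
        expected = cs / (1 - np.exp(2 * fit.loglik_null / n))
        assert nagelkerke_r2(fit) == pytest.approx(expected, rel=1e-12)
        assert pseudo_r2(fit, kind="cox_snell") == pytest.approx(cs, rel=1e-12)
        assert 0 < nagelkerke_r2(fit) < 1

    def test_monotone_in_nested_fits(self, rng):
        X, y = _simulate_po(rng, 2000, beta=[0.6, 0.3])
        f_small = fit_proportional_odds(X[:, :1], y)
        f_big = fit_proportional_odds(X, y)
        assert nagelkerke_r2(f_big) >= nagelkerke_r2(f_small) - 1e-12

    def test_mcfadden_flavor(self, rng):
        X, y = _simulate_po(rng, 1000, beta=[0.8])
        fit = fit_proportional_odds(X, y)
        assert pseudo_r2(fit, kind="mcfadden") == pytest.approx(
            1 - fit.loglik / fit.loglik_null, rel=1e-12)
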