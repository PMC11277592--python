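"""Maximum-likelihood fitting: closed forms, oracles, and invariances."""

import numpy as np
import pytest
from scipy.stats import kstest

from repsieve import CollinearityError, cox_loglik, fit_cox, fit_logistic
from repsieve.regression import wald_neglog10p


def _bernoulli(rng, eta):
    return (rng.random(len(eta)) < 1.0 / (1.0 + np.exp(-eta))).astype(int)


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(np.empty((100, 0)), y)
        assert fit.converged
        assert fit.intercept == pytest.approx(np.log(30 / 70), abs=1e-8)
        assert fit.loglik == pytest.approx(
            30 * np.log(0.3) + 70 * np.log(0.7), abs=1e-8
        )

    def test_two_by_two_log_odds_ratio(self):
        # exposure x outcome counts a=40, b=10, c=10, d=40
        x = np.r_[np.ones(50), np.zeros(50)]
        y = np.r_[np.ones(40), np.zeros(10), np.ones(10), np.zeros(40)]
        fit = fit_logistic(x[:, None], y)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(np.log(16), abs=1e-6)
        # grid maximization oracle over (b0, b1)
        b0g = np.linspace(-2, 2, 161)
        b1g = np.linspace(0, 4, 161)
        B0, B1 = np.meshgrid(b0g, b1g, indexing="ij")
        eta = B0[..., None] + B1[..., None] * x[None, None, :]
        ll = (eta * y).sum(-1) - np.logaddexp(0, eta).sum(-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert fit.coef[0] == pytest.approx(b1g[j], abs=0.05)
        assert fit.intercept == pytest.approx(b0g[i], abs=0.05)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.standard_normal((150, 3))
        y = _bernoulli(rng, X @ [0.5, -1.0, 0.2])
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coef], ref.params, atol=1e-6
        )
        np.testing.assert_allclose(
            np.r_[fit.intercept_se, fit.se], ref.bse, atol=1e-6
        )
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(100)
        pvals = []
        for _ in range(300):
            X = rng.standard_normal((120, 1))
            y = rng.integers(0, 2, 120)
            pvals.append(fit_logistic(X, y).p_values[0])
        assert kstest(pvals, "uniform").pvalue > 1e-3

    def test_local_maximum(self, rng):
        X = rng.standard_normal((120, 2))
        y = _bernoulli(rng, X @ [1.0, -0.5])
        fit = fit_logistic(X, y)
        theta = np.r_[fit.intercept, fit.coef]
        A = np.column_stack([np.ones(120), X])

        def ll(t):
            eta = A @ t
            return eta @ y - np.logaddexp(0, eta).sum()

        base = ll(theta)
        for _ in range(20):
            assert ll(theta + rng.normal(0, 1e-3, 3)) <= base + 1e-12

    def test_affine_rescaling_invariance(self, rng):
        X = rng.standard_normal((150, 2))
        y = _bernoulli(rng, X @ [0.8, -0.3])
        f1 = fit_logistic(X, y)
        Xs = X.copy()
        Xs[:, 0] *= 10.0
        f2 = fit_logistic(Xs, y)
        assert f2.coef[0] == pytest.approx(f1.coef[0] / 10.0, rel=1e-6)
        assert f2.p_values[0] == pytest.approx(f1.p_values[0], rel=1e-6)

    def test_separation_flagged_not_silent(self):
        x = np.r_[np.ones(10), np.zeros(10)]
        y = x.astype(int)
        fit = fit_logistic(x[:, None], y)
        assert not fit.converged

    def test_rank_deficiency_names_columns(self, rng):
        X = rng.standard_normal((50, 2))
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(CollinearityError) as err:
            fit_logistic(X, rng.integers(0, 2, 50), ["a", "b", "a_copy"])
        assert set(err.value.offending) & {"a", "a_copy"}

    def test_too_many_covariates(self, rng):
        with pytest.raises(ValueError, match="fewer covariates"):
            fit_logistic(rng.standard_normal((5, 6)), np.ones(5))


class TestCox:
    def test_matches_partial_likelihood_grid(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(6)
        t = np.arange(1.0, 7.0)
        ev = np.ones(6)
        fit = fit_cox(z[:, None], t, ev)
        grid = np.linspace(-5, 5, 100001)
        lls = np.array([cox_loglik(z[:, None], t, ev, [b]) for b in
                        np.linspace(-5, 5, 2001)])
        coarse = np.linspace(-5, 5, 2001)[np.argmax(lls)]
        fine = np.linspace(coarse - 0.01, coarse + 0.01, 2001)
        lls = np.array([cox_loglik(z[:, None], t, ev, [b]) for b in fine])
        assert fit.coef[0] == pytest.approx(fine[np.argmax(lls)], abs=1e-4)

    def test_matches_lifelines_with_ties(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        n = 90
        X = rng.standard_normal((n, 3))
        t = rng.integers(1, 9, n).astype(float)     # heavy ties -> Efron
        ev = rng.integers(0, 2, n)
        ev[0] = 1
        fit = fit_cox(X, t, ev)
        df = pd.DataFrame(np.column_stack([t, ev, X]),
                          columns=["t", "e", "a", "b", "c"])
        ref = lifelines.CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coef, ref.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.values, atol=1e-5)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_time_rank_invariance(self, rng):
        n = 100
        X = rng.standard_normal((n, 2))
        t = rng.exponential(10, n) + 0.1
        ev = rng.integers(0, 2, n)
        ev[:5] = 1
        f1 = fit_cox(X, t, ev)
        f2 = fit_cox(X, np.log(t + 1.0), ev)     # strictly monotone transform
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-8)

    def test_constant_covariate_rejected(self, rng):
        n = 30
        with pytest.raises(CollinearityError):
            fit_cox(np.ones((n, 1)), rng.exponential(1, n) + 0.1,
                    np.ones(n), ["const"])

    def test_no_events_rejected(self, rng):
        with pytest.raises(ValueError, match="no events"):
            fit_cox(rng.standard_normal((20, 1)), np.arange(1.0, 21.0),
                    np.zeros(20))

    def test_monotone_likelihood_flagged(self):
        # covariate perfectly ordering event times: beta diverges
        n = 12
        z = np.arange(n, dtype=float)
        t = np.arange(1.0, n + 1)
        fit = fit_cox(-z[:, None], t, np.ones(n))
        assert not fit.converged

    def test_null_mean_beta_near_zero(self):
        rng = np.random.default_rng(5)
        betas = []
        for _ in range(150):
            z = rng.integers(0, 2, 60).astype(float)
            t = rng.exponential(5, 60) + 0.01
            betas.append(fit_cox(z[:, None], t, np.ones(60)).coef[0])
        assert abs(np.mean(betas)) < 3 * np.std(betas) / np.sqrt(len(betas)) + 0.05

    def test_local_maximum(self, rng):
        n = 80
        X = rng.standard_normal((n, 2))
        t = rng.exponential(5, n) + 0.01
        ev = np.ones(n)
        fit = fit_cox(X, t, ev)
        base = cox_loglik(X, t, ev, fit.coef)
        for _ in range(20):
            pert = fit.coef + rng.normal(0, 1e-3, 2)
            assert cox_loglik(X, t, ev, pert) <= base + 1e-12


def test_neglog10p_extreme_z_no_underflow():
    val = wald_neglog10p(10.0, 1.0)
    assert val == pytest.approx(-np.log10(2 * 7.619853e-24), rel=1e-4)
    assert np.isfinite(wald_neglog10p(40.0, 1.0))
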