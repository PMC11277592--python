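"""Synthetic DGP: covariance structure, outcomes, censoring calibration."""

import numpy as np
import pytest
from dataclasses import replace

from repsieve import (
    SimConfig,
    calibrate_censoring,
    fit_cox,
    fit_logistic,
    gen_binary_outcome,
    gen_features,
    gen_survival_outcome,
    holdout_split,
    place_true_features,
    simulate_dataset,
)


class TestConfig:
    def test_defaults_mirror_study_design(self):
        cfg = SimConfig()
        assert (cfg.n, cfg.m, cfg.block_len, cfg.rho, cfg.m1) == (
            400, 10_000, 20, 0.2, 6,
        )
        assert cfg.beta_magnitude == 2.0
        assert SimConfig(family="survival").beta_magnitude == 0.7

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"m": 101},                      # not divisible by block_len
            {"m1": 5},                       # odd
            {"rho": 1.0},
            {"rho": -0.1},
            {"m": 40, "m1": 6},              # not enough blocks
            {"family": "poisson"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestFeatures:
    def test_independent_when_rho_zero(self):
        cfg = SimConfig(n=2000, m=40, rho=0.0, m1=2, seed=1)
        X = gen_features(cfg)
        corr = np.corrcoef(X, rowvar=False)
        off = corr[~np.eye(40, dtype=bool)]
        assert np.abs(off).max() < 0.12

    def test_block_compound_symmetry(self):
        cfg = SimConfig(n=5000, m=200, rho=0.2, seed=2)
        X = gen_features(cfg)
        corr = np.corrcoef(X, rowvar=False)
        within, cross = [], []
        for b in range(10):
            blk = slice(b * 20, (b + 1) * 20)
            sub = corr[blk, blk]
            within.append(sub[~np.eye(20, dtype=bool)].mean())
            if b:
                cross.append(np.abs(corr[blk, 0:20]).mean())
        assert np.mean(within) == pytest.approx(0.2, abs=0.02)
        assert np.mean(cross) < 0.03
        assert np.allclose(np.diag(np.cov(X, rowvar=False)), 1.0, atol=0.15)

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n=50, m=100, seed=9)
        np.testing.assert_array_equal(gen_features(cfg), gen_features(cfg))


class TestPlacement:
    def test_alternating_signs_binary(self):
        truth = place_true_features(SimConfig())
        np.testing.assert_array_equal(truth.true_betas, [2, -2, 2, -2, 2, -2])

    def test_alternating_signs_survival(self):
        truth = place_true_features(SimConfig(family="survival"))
        np.testing.assert_allclose(
            truth.true_betas, [0.7, -0.7, 0.7, -0.7, 0.7, -0.7]
        )

    def test_pairs_share_blocks(self):
        cfg = SimConfig(m=200, randomize_placement=True, seed=4)
        truth = place_true_features(cfg)
        blocks = truth.true_cols // cfg.block_len
        assert len(truth.true_ids) == 6
        # consecutive pairs in the same block, three distinct blocks
        assert blocks[0] == blocks[1] and blocks[2] == blocks[3]
        assert blocks[4] == blocks[5]
        assert len(set(blocks)) == 3

    def test_minimal_pair(self):
        truth = place_true_features(SimConfig(m=20, m1=2))
        assert len(truth.true_ids) == 2


class TestBinaryOutcome:
    def test_zero_covariates_give_half(self, rng):
        truth = place_true_features(SimConfig(m=200))
        y = gen_binary_outcome(np.zeros((20000, 6)), truth, rng)
        assert y.mean() == pytest.approx(0.5, abs=0.02)

    def test_marginal_response_rate_half_by_symmetry(self):
        # beta'z is symmetric around 0, so E[expit(beta'z)] = 1/2 exactly
        ds, _ = simulate_dataset(SimConfig(n=4000, m=200, seed=6))
        assert ds.y.mean() == pytest.approx(0.5, abs=0.03)


class TestSurvivalOutcome:
    def test_exponential_mean_without_censoring(self, rng):
        cfg = SimConfig(family="survival", m=200, censor_target=None,
                        beta_magnitude=0.0)
        truth = place_true_features(cfg)
        t, ev = gen_survival_outcome(np.zeros((20000, 6)), truth, cfg, rng)
        assert ev.all()
        assert t.mean() == pytest.approx(1 / cfg.baseline_hazard, rel=0.05)

    def test_uncalibrated_config_rejected(self, rng):
        cfg = SimConfig(family="survival", m=200, censor_target=0.30)
        truth = place_true_features(cfg)
        with pytest.raises(ValueError, match="calibrat"):
            gen_survival_outcome(rng.standard_normal((10, 6)), truth, cfg, rng)

    @pytest.mark.parametrize("target", [0.30, 0.10])
    def test_calibration_hits_target(self, target):
        cfg = SimConfig(family="survival", m=200, censor_target=target, seed=0)
        a, b = calibrate_censoring(cfg, target)
        cfg = replace(cfg, censor_a=a, censor_b=b, n=20000)
        ds, _ = simulate_dataset(cfg)          # independent verification draw
        assert 1 - ds.event.mean() == pytest.approx(target, abs=0.01)

    def test_two_stage_reuses_accrual_window(self):
        cfg = SimConfig(family="survival", m=200)
        a30, b30 = calibrate_censoring(cfg, 0.30)
        a10, b10 = calibrate_censoring(cfg, 0.10)
        assert b30 is None
        assert a10 == pytest.approx(a30)
        assert b10 is not None and b10 > 0

    def test_censoring_fraction_decreasing_in_window(self):
        from repsieve.simulate import _calibration_lambdas, _censor_frac_uniform, _risk_sd

        cfg = SimConfig(family="survival", m=200)
        lam = _calibration_lambdas(cfg.baseline_hazard, _risk_sd(cfg))
        fr = [_censor_frac_uniform(a, lam) for a in (1.0, 5.0, 25.0, 125.0)]
        assert fr == sorted(fr, reverse=True)

    def test_calibration_reproducible(self):
        cfg = SimConfig(family="survival", m=200)
        assert calibrate_censoring(cfg, 0.30) == calibrate_censoring(cfg, 0.30)

    def test_same_seed_shares_latent_event_times(self):
        c30 = SimConfig(family="survival", n=500, m=200, censor_target=0.30, seed=3)
        c10 = SimConfig(family="survival", n=500, m=200, censor_target=0.10, seed=3)
        d30, _ = simulate_dataset(c30)
        d10, _ = simulate_dataset(c10)
        both = d30.event.astype(bool) & d10.event.astype(bool)
        assert both.any()
        np.testing.assert_allclose(d30.time[both], d10.time[both])


class TestHoldout:
    def test_even_split(self):
        tr, va = holdout_split(400, seed=1)
        assert (len(tr), len(va)) == (200, 200)
        assert np.array_equal(np.sort(np.r_[tr, va]), np.arange(400))

    def test_odd_split_favours_training(self):
        tr, va = holdout_split(5, seed=1)
        assert (len(tr), len(va)) == (3, 2)

    def test_deterministic(self):
        assert np.array_equal(holdout_split(100, 7)[0], holdout_split(100, 7)[0])


class TestParameterRecovery:
    """Oracle fits on large samples recover the planted coefficients.

    Single fixed-seed realizations checked coefficient-wise at a
    multiplicity-aware 3-SE band (6 coefficients x 2 families)."""

    def test_binary_recovery(self):
        cfg = SimConfig(family="binary", n=4000, m=120, seed=0)
        ds, truth = simulate_dataset(cfg)
        fit = fit_logistic(ds.columns(truth.true_ids), ds.y, truth.true_ids)
        z = (fit.coef - truth.true_betas) / fit.se
        assert np.abs(z).max() < 3.0

    def test_survival_recovery(self):
        cfg = SimConfig(family="survival", n=4000, m=120, seed=0,
                        censor_target=None)
        ds, truth = simulate_dataset(cfg)
        fit = fit_cox(ds.columns(truth.true_ids), ds.time, ds.event,
                      truth.true_ids)
        z = (fit.coef - truth.true_betas) / fit.se
        assert np.abs(z).max() < 3.0
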