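"""Unit and property tests for the Gaussian / beta-divergence estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from betanova import (
    BetaConfig,
    DegenerateVarianceError,
    beta_estimate,
    beta_estimate_batch,
    beta_weight,
    detect_outliers,
    hybrid_estimate,
    mle_estimate,
    predicted_weight_quantile,
)
from betanova.estimators import GaussianParams, pooled_robust_scale


class TestMLE:
    def test_hand_computed_example(self):
        params = mle_estimate([0, 0, 3, 3])
        assert params.mean == pytest.approx(1.5)
        assert params.variance == pytest.approx(2.25)  # sum (x-1.5)^2 / 4
        assert params.source == "mle"
        assert params.iterations == 0

    def test_symmetric_pair(self):
        c, delta = 7.3, 0.4
        assert mle_estimate([c, c + delta]).mean == pytest.approx(c + delta / 2)

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            mle_estimate([2, 2, 2, 2])

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            mle_estimate([1.0])


class TestBetaWeight:
    def test_examples(self):
        assert beta_weight(5.0, 5.0, 0.3, 0.2) == pytest.approx(1.0)
        assert beta_weight(123.4, 5.0, 0.3, 0.0) == pytest.approx(1.0)
        # direct evaluation: exp(-0.2 * 9 / 2) = exp(-0.9)
        assert beta_weight(3.0, 0.0, 1.0, 0.2) == pytest.approx(np.exp(-0.9))

    # ranges keep the exponent above float64 underflow, where W > 0 holds
    @settings(max_examples=200, derandomize=True)
    @given(
        x=st.floats(-10, 10),
        mean=st.floats(-10, 10),
        var=st.floats(1.0, 1e3),
        beta=st.floats(1e-3, 2.0),
    )
    def test_weight_range_property(self, x, mean, var, beta):
        w = beta_weight(x, mean, var, beta)
        assert 0.0 < w <= 1.0
        if abs(x - mean) > 1e-6:
            assert w < 1.0
        if x == mean:
            assert w == 1.0


class TestPredictedWeightQuantile:
    def test_closed_form_matches_chi2_pivot(self):
        delta = predicted_weight_quantile(0.2, 1e-5)
        assert delta == pytest.approx(
            np.exp(-0.1 * stats.chi2.ppf(1 - 1e-5, df=1))
        )
        assert delta == pytest.approx(0.1421, abs=2e-3)

    def test_whole_support_limit(self):
        assert predicted_weight_quantile(0.2, 1 - 1e-12) == pytest.approx(1.0, abs=1e-5)

    def test_monte_carlo_calibration(self, rng):
        # empirical P(W <= delta) under the null within 3 MC standard errors
        tail = 1e-3
        n = 1_000_000
        z = rng.standard_normal(n)
        w = np.exp(-0.1 * z**2)
        delta = predicted_weight_quantile(0.2, tail)
        hit = np.mean(w <= delta)
        se = np.sqrt(tail * (1 - tail) / n)
        assert abs(hit - tail) < 3 * se


class TestBetaEstimate:
    def test_beta_to_zero_limit_recovers_mle(self, rng):
        x = rng.normal(3, 0.5, 20)
        tiny = BetaConfig(beta=1e-9)
        robust = beta_estimate(x, tiny)
        mle = mle_estimate(x)
        assert robust.mean == pytest.approx(mle.mean, abs=1e-6)
        assert robust.variance == pytest.approx(mle.variance, rel=1e-6)

    def test_monte_carlo_consistency(self, rng, config):
        x = rng.normal(5.0, np.sqrt(0.05), 10_000)
        params = beta_estimate(x, config)
        assert params.converged
        assert params.mean == pytest.approx(5.0, abs=0.01)
        assert params.variance == pytest.approx(0.05, rel=0.10)

    def test_outlier_downweighted(self, config):
        x = [2.0, 2.1, 1.9, 50.0]
        robust = beta_estimate(x, config)
        assert abs(robust.mean - 2.0) < 0.2
        assert mle_estimate(x).mean == pytest.approx(14.0)

    def test_matches_hand_iteration_oracle(self, config):
        # independent plain-python reimplementation of the reweighting updates
        x = np.array([2.0, 2.1, 1.9, 50.0])
        mu = float(np.median(x))
        var = (1.4826 * float(np.median(np.abs(x - mu)))) ** 2
        for _ in range(200):
            w = np.exp(-config.beta * (x - mu) ** 2 / (2 * var))
            mu_new = float((w * x).sum() / w.sum())
            var_new = float((config.beta + 1) * (w * (x - mu) ** 2).sum() / w.sum())
            if max(abs(mu_new - mu), abs(var_new - var)) < config.tol:
                mu, var = mu_new, var_new
                break
            mu, var = mu_new, var_new
        params = beta_estimate(x, config)
        assert params.mean == pytest.approx(mu, abs=1e-5)
        assert params.variance == pytest.approx(var, rel=1e-4)

    def test_batch_matches_scalar(self, rng, config):
        X = rng.normal(4.0, 0.5, size=(40, 8))
        mu, var, iters, conv, degen = beta_estimate_batch(X, config)
        assert not degen.any()
        for i in range(40):
            p = beta_estimate(X[i], config)
            assert p.mean == pytest.approx(mu[i], abs=1e-10)
            assert p.variance == pytest.approx(var[i], rel=1e-10)
            assert p.iterations == iters[i]

    def test_convergence_rate_on_clean_samples(self, rng, config):
        n_ok = 0
        trials = 1000
        for _ in range(trials):
            n = int(rng.integers(3, 12))
            x = rng.normal(0.0, 1.0, n)
            n_ok += beta_estimate(x, config).converged
        assert n_ok / trials >= 0.99


class TestDetectOutliers:
    def test_values_at_mean_never_flagged(self, config):
        params = GaussianParams(mean=3.0, variance=0.05, source="beta", iterations=1)
        wv, mask = detect_outliers([3.0, 3.0, 3.0], params, config)
        assert not mask.any()
        assert np.allclose(wv.weights, 1.0)

    def test_single_extreme_value_flagged(self, config):
        x = [2.0, 2.1, 1.9, 50.0]
        params = beta_estimate(x, config)
        wv, mask = detect_outliers(x, params, config)
        assert mask.tolist() == [False, False, False, True]
        assert wv.weights[3] <= wv.threshold

    def test_clean_flag_rate_matches_tail_prob(self, rng):
        cfg = BetaConfig(tail_prob=1e-3)
        x = rng.normal(0.0, 1.0, 100_000)
        params = beta_estimate(x, cfg)
        _, mask = detect_outliers(x, params, cfg)
        rate = mask.mean()
        se = np.sqrt(1e-3 * (1 - 1e-3) / x.size)
        assert abs(rate - 1e-3) < 3 * se


class TestHybrid:
    def test_clean_sample_uses_mle_exactly(self, rng, config):
        x = rng.normal(3.0, np.sqrt(0.05), 15)
        params, mask = hybrid_estimate(x, config)
        mle = mle_estimate(x)
        assert params.source == "mle"
        assert not mask.any()
        assert params.mean == mle.mean and params.variance == mle.variance

    def test_contaminated_sample_uses_beta(self, rng, config):
        x = np.append(rng.normal(3.0, np.sqrt(0.05), 9), 12.0)
        params, mask = hybrid_estimate(x, config)
        assert params.source == "beta"
        assert mask[-1]

    def test_beta_zero_is_mle(self, rng):
        x = np.append(rng.normal(3.0, 0.2, 9), 12.0)
        params, mask = hybrid_estimate(x, BetaConfig(beta=0.0))
        mle = mle_estimate(x)
        assert params.source == "mle"
        assert params.mean == mle.mean and not mask.any()

    def test_bounded_influence(self, rng, config):
        base = rng.normal(0.0, 1.0, 10)
        contaminants = [1e1, 1e2, 1e4, 1e6]
        beta_means, mle_means = [], []
        for c in contaminants:
            x = np.append(base, c)
            beta_means.append(beta_estimate(x, config).mean)
            mle_means.append(mle_estimate(x).mean)
        # robust mean barely moves while the MLE grows without bound
        assert max(beta_means) - min(beta_means) < 0.01
        assert np.all(np.diff(mle_means) > 0)
        assert mle_means[-1] > 1e4

    def test_variance_efficiency_on_clean_data(self, rng, config):
        # the (beta+1) factor keeps the scale estimate ~unbiased for Gaussians
        sigma2 = 0.05
        estimates = []
        for _ in range(1000):
            x = rng.normal(0.0, np.sqrt(sigma2), 100)
            estimates.append(beta_estimate(x, config).variance)
        assert np.mean(estimates) == pytest.approx(sigma2, rel=0.05)


class TestPooledScale:
    def test_recovers_common_variance(self, rng):
        X = rng.normal(3.0, np.sqrt(0.05), size=(400, 6))
        idx = [np.arange(3), np.arange(3, 6)]
        scale = pooled_robust_scale(X, idx)
        assert np.median(scale) == pytest.approx(0.05, rel=0.25)

    def test_robust_to_one_outlier(self, rng):
        X = rng.normal(3.0, np.sqrt(0.05), size=(200, 6))
        clean = pooled_robust_scale(X, [np.arange(3), np.arange(3, 6)])
        X[:, 2] = 12.0
        dirty = pooled_robust_scale(X, [np.arange(3), np.arange(3, 6)])
        assert np.median(dirty) < 10 * np.median(clean)
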