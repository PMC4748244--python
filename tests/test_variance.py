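"""Logit transforms, REML variance decomposition, sample estimates, bias."""

import numpy as np
import pandas as pd
import pytest

from cytostand.simulate import simulate_proportion_model
from cytostand.variance import (
    anova_components,
    bias,
    corrected_proportion,
    fit_variance_components,
    inv_logit,
    logit,
    observations_from_table,
    sample_level_estimates,
)


class TestLogit:
    def test_reference_values(self):
        assert logit(np.array([0.5]))[0] == 0.0
        np.testing.assert_allclose(logit(np.array([0.1]))[0], np.log(1 / 9), atol=1e-12)

    def test_inverse_pair_on_grid(self):
        p = np.linspace(0.001, 0.999, 500)
        np.testing.assert_allclose(inv_logit(logit(p)), p, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            logit(np.array([0.0]))
        with pytest.raises(ValueError):
            logit(np.array([1.2]))

    def test_count_correction_handles_zero_counts(self):
        p = corrected_proportion(np.array([0, 10]), np.array([100, 100]))
        np.testing.assert_allclose(p, [0.5 / 101, 10.5 / 101])
        y = logit(p)
        assert np.isfinite(y).all()

    def test_observations_from_table(self):
        table = pd.DataFrame(
            {"sample": [0], "center": [0], "replicate": [0], "count": [25],
             "denominator_count": [100]}
        )
        obs = observations_from_table(table)
        np.testing.assert_allclose(obs["y"], logit(np.array([25.5 / 101])))


def _balanced_y(alpha, beta, eps=None, mu=0.0):
    a, b = len(alpha), len(beta)
    r = 1 if eps is None else eps.shape[2]
    rows = []
    for i in range(a):
        for j in range(b):
            for k in range(r):
                e = 0.0 if eps is None else eps[i, j, k]
                rows.append({"sample": i, "center": j, "replicate": k,
                             "y": mu + alpha[i] + beta[j] + e})
    return pd.DataFrame(rows)


class TestVarianceComponents:
    def test_noise_free_decomposition_is_exact(self, rng):
        # with zero residual the moment estimator returns the empirical
        # variances of the injected effects at machine precision
        alpha = rng.normal(0, 0.7, 4)
        beta = rng.normal(0, 0.4, 6)
        obs = _balanced_y(alpha, beta)
        obs = pd.concat([obs, obs.assign(replicate=1)], ignore_index=True)  # r=2
        m = anova_components(obs)
        assert m["sigma2_residual"] == pytest.approx(0.0, abs=1e-12)
        assert m["sigma2_sample"] == pytest.approx(np.var(alpha, ddof=1), abs=1e-10)
        assert m["sigma2_center"] == pytest.approx(np.var(beta, ddof=1), abs=1e-10)

    def test_reml_equals_anova_on_balanced_interior_fits(self):
        checked = 0
        for seed in range(10):
            df = simulate_proportion_model(
                -1.0, 0.5, 0.3, 0.2, rng=np.random.default_rng(seed)
            )
            m = anova_components(df)
            if not all(v > 0 for v in m.values()):
                continue
            c = fit_variance_components(df)
            assert c.sigma2_sample == pytest.approx(m["sigma2_sample"], abs=1e-6)
            assert c.sigma2_center == pytest.approx(m["sigma2_center"], abs=1e-6)
            assert c.sigma2_residual == pytest.approx(m["sigma2_residual"], abs=1e-6)
            checked += 1
        assert checked >= 5

    def test_null_center_component_shrinks_to_boundary(self):
        hits = 0
        for seed in range(20):
            df = simulate_proportion_model(
                -1.0, 0.5, 0.0, 0.2, rng=np.random.default_rng(100 + seed)
            )
            c = fit_variance_components(df)
            hits += c.sigma2_center < 0.01
        assert hits >= 18

    def test_anova_returns_nan_for_unbalanced(self):
        df = simulate_proportion_model(0.0, 0.3, 0.3, 0.3, rng=np.random.default_rng(0))
        df = df.iloc[:-1]
        assert np.isnan(anova_components(df)["sigma2_sample"])

    def test_requires_two_samples_and_centers(self):
        df = simulate_proportion_model(
            0.0, 0.3, 0.3, 0.3, n_samples=1, rng=np.random.default_rng(0)
        )
        with pytest.raises(ValueError, match="at least 2"):
            fit_variance_components(df)

    def test_estimates_nonnegative_and_deterministic(self):
        df = simulate_proportion_model(-2.0, 0.1, 0.4, 0.3, rng=np.random.default_rng(5))
        a = fit_variance_components(df)
        b = fit_variance_components(df)
        for v in (a.sigma2_sample, a.sigma2_center, a.sigma2_residual):
            assert v >= 0
        assert a.as_dict() == b.as_dict()


class TestSampleLevelEstimates:
    def test_noiseless_limit_reproduces_sample_means(self):
        obs = _balanced_y(np.array([0.3, -0.2, 0.1]), np.zeros(4))
        est = sample_level_estimates(obs)
        np.testing.assert_allclose(est["y_hat"], [0.3, -0.2, 0.1], atol=1e-6)
        assert (est["se"] < 1e-3).all()

    def test_ci_contains_point_and_back_transform_is_ordered(self):
        df = simulate_proportion_model(-1.5, 0.5, 0.3, 0.2, rng=np.random.default_rng(1))
        est = sample_level_estimates(df)
        assert ((est["y_lo"] <= est["y_hat"]) & (est["y_hat"] <= est["y_hi"])).all()
        assert ((est["p_lo"] <= est["p_hat"]) & (est["p_hat"] <= est["p_hi"])).all()
        assert ((est["p_lo"] > 0) & (est["p_hi"] < 1)).all()

    def test_more_replicates_shrink_intervals(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            small = simulate_proportion_model(-1.0, 0.4, 0.3, 0.4, 3, 9, 2, rng)
            rng = np.random.default_rng(seed)
            big = simulate_proportion_model(-1.0, 0.4, 0.3, 0.4, 3, 9, 8, rng)
            w_small = (sample_level_estimates(small)["y_hi"] - sample_level_estimates(small)["y_lo"]).mean()
            w_big = (sample_level_estimates(big)["y_hi"] - sample_level_estimates(big)["y_lo"]).mean()
            wins += w_big < w_small
        assert wins >= 18


class TestBias:
    def test_self_comparison_is_zero_and_insignificant(self):
        df = simulate_proportion_model(-1.0, 0.5, 0.3, 0.2, rng=np.random.default_rng(2))
        est = sample_level_estimates(df)
        b = bias(est, est)
        assert (b["delta"] == 0).all()
        assert not b["significant"].any()

    def test_antisymmetric(self):
        r = np.random.default_rng(3)
        e1 = sample_level_estimates(simulate_proportion_model(-1.0, 0.5, 0.3, 0.2, rng=r))
        e2 = sample_level_estimates(simulate_proportion_model(-0.5, 0.5, 0.3, 0.2, rng=r))
        fwd, rev = bias(e1, e2), bias(e2, e1)
        np.testing.assert_allclose(fwd["delta"], -rev["delta"], atol=1e-12)
        assert (fwd["significant"] == rev["significant"]).all()

    def test_injected_shift_recovered(self):
        df = simulate_proportion_model(-1.0, 0.5, 0.3, 0.2, rng=np.random.default_rng(4))
        shifted = df.copy()
        shifted["y"] = shifted["y"] + 0.5
        b = bias(sample_level_estimates(shifted), sample_level_estimates(df))
        np.testing.assert_allclose(b["delta"], 0.5, atol=1e-8)
        assert ((b["lo"] <= 0.5) & (0.5 <= b["hi"])).all()

    def test_sample_present_in_one_method_flagged_missing(self):
        df = simulate_proportion_model(-1.0, 0.5, 0.3, 0.2, rng=np.random.default_rng(5))
        e_full = sample_level_estimates(df)
        e_partial = sample_level_estimates(df[df["sample"] < 2])
        b = bias(e_full, e_partial)
        assert b.loc[b["sample"] == 2, "missing"].all()
        assert not b.loc[b["sample"] < 2, "missing"].any()
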