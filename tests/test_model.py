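"""Maximum-likelihood fitting, Wald odds-ratio tables, and the attenuation
property that motivates Bridge random intercepts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from bridgejoint.bridge import sample_bridge
from bridgejoint.design import build_design
from bridgejoint.model import (BridgeMultinomial, JointBridgeMultinomial,
                               fit_joint, fit_univariate)
from bridgejoint.results import wald_intervals

from conftest import binary_spec, simulate_joint


@pytest.fixture(scope="module")
def small_fit(small_cohort):
    df, truth, spec = small_cohort
    return fit_joint(df, spec, nodes=15), truth


def _copy_fit(fit):
    import dataclasses
    return dataclasses.replace(fit, params=fit.params.copy(),
                               params_flat=fit.params_flat.copy(),
                               cov_flat=fit.cov_flat.copy())


class TestWaldIntervals:
    def test_null_coefficient(self, small_fit):
        fit, _ = small_fit
        # inject a known coefficient/se and check the arithmetic
        fit2 = _copy_fit(fit)
        i = fit2._slope_index(1, 0, 0)
        fit2.params_flat[i] = 0.0
        fit2.params.alpha[0, 0] = 0.0
        fit2.cov_flat[i, i] = 0.1**2
        row = fit2.or_table().iloc[0]
        assert row.OR == pytest.approx(1.0)
        assert row.ci_low == pytest.approx(np.exp(-1.959964 * 0.1), rel=1e-4)
        assert row.ci_high == pytest.approx(np.exp(+1.959964 * 0.1), rel=1e-4)
        assert row.p == pytest.approx(1.0)

    def test_doubling_odds_ratio(self, small_fit):
        fit, _ = small_fit
        fit = _copy_fit(fit)
        i = fit._slope_index(1, 0, 0)
        fit.params_flat[i] = np.log(2.0)
        fit.params.alpha[0, 0] = np.log(2.0)
        fit.cov_flat[i, i] = 0.2**2
        row = fit.or_table().iloc[0]
        assert row.OR == pytest.approx(2.0, rel=1e-6)
        assert row.ci_low == pytest.approx(np.exp(np.log(2) - 1.959964 * 0.2),
                                           rel=1e-4)
        assert row.ci_high == pytest.approx(np.exp(np.log(2) + 1.959964 * 0.2),
                                            rel=1e-4)

    def test_ci_excludes_one_iff_significant(self, small_fit):
        fit, _ = small_fit
        tab = wald_intervals(fit, 0.95).dropna(subset=["p"])
        excludes = (tab.ci_low > 1.0) | (tab.ci_high < 1.0)
        np.testing.assert_array_equal(excludes.to_numpy(),
                                      (tab.p < 0.05).to_numpy())


def test_joint_fit_recovers_truth_within_wald_bands(small_fit):
    fit, truth = small_fit
    assert fit.converged
    tab = fit.or_table()
    row = tab[(tab.outcome == "gestational_age")
              & (tab.contrast == "preterm vs term")].iloc[0]
    assert abs(row.coef - np.log(4)) < 3 * row.se
    assert abs(fit.params.phi1 - truth.phi1) < 0.25
    assert abs(fit.params.rho - truth.rho) < 0.35


def test_fixed_rho_zero_equals_sum_of_univariate_fits():
    df, truth, spec = simulate_joint(5, n_clusters=12, cluster_size=40,
                                     truth=None)
    joint = fit_joint(df, spec, nodes=15, fix_rho=0.0, compute_cov=False)
    f1 = fit_univariate(df, "x", "gestational_age", spec, nodes=15,
                        compute_cov=False)
    f2 = fit_univariate(df, "x", "birth_weight", spec, nodes=15,
                        compute_cov=False)
    assert joint.loglik == pytest.approx(f1.loglik + f2.loglik, abs=1e-4)


def test_degenerate_designs_raise_named_errors(small_cohort):
    df, _, spec = small_cohort
    bad = df.copy()
    bad["x"] = 0
    with pytest.raises(ValueError, match="constant"):
        fit_joint(bad, spec, nodes=15)
    dup = df.copy()
    dup["x2"] = dup["x"]
    spec2 = spec.with_predictors(["x", "x2"], ["x"])
    with pytest.raises(ValueError, match="rank deficient"):
        fit_joint(dup, spec2, nodes=15)


def test_estimates_invariant_to_row_order_and_cluster_labels(small_cohort):
    df, _, spec = small_cohort
    base = fit_joint(df, spec, nodes=15, compute_cov=False)
    shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
    shuffled["hospital"] = shuffled["hospital"].map(
        lambda h: f"relabel_{h}")
    other = fit_joint(shuffled, spec, nodes=15, compute_cov=False)
    np.testing.assert_allclose(other.params_flat, base.params_flat, atol=1e-6)
    assert other.loglik == pytest.approx(base.loglik, abs=1e-8)


def test_univariate_null_and_signal():
    df, truth, spec = simulate_joint(31, n_clusters=30, cluster_size=60)
    strong = fit_univariate(df, "x", "gestational_age", spec, nodes=15,
                            compute_cov=False)
    null = fit_univariate(df, None, "gestational_age", spec, nodes=15,
                          compute_cov=False)
    assert 2 * (strong.loglik - null.loglik) > 20  # overwhelming LRT signal
    # permuted predictor carries no information
    rng = np.random.default_rng(0)
    perm = df.copy()
    perm["x"] = rng.permutation(perm["x"].to_numpy())
    f_perm = fit_univariate(perm, "x", "gestational_age", spec, nodes=15,
                            compute_cov=False)
    assert 2 * (f_perm.loglik - null.loglik) < 9.0


def test_unconverged_fit_refuses_wald_table(small_fit):
    fit, _ = small_fit
    sick = type(fit)(model=fit.model, params=fit.params,
                     params_flat=fit.params_flat, cov_flat=fit.cov_flat,
                     loglik=fit.loglik, converged=False, n_obs=fit.n_obs,
                     n_clusters=fit.n_clusters)
    with pytest.raises(ValueError, match="converged"):
        wald_intervals(sick)


def test_summary_mentions_key_quantities(small_fit):
    fit, _ = small_fit
    text = fit.summary()
    for token in ("log-likelihood", "phi1", "rho", "preterm vs term"):
        assert token in text


def test_marginal_fit_attenuates_conditional_slope_by_phi():
    """Binary collapse: a cluster-ignoring logistic regression estimates
    phi times the conditional slope — the Bridge marginalization property."""
    rng = np.random.default_rng(42)
    ncl, m, phi, b, w0 = 3000, 5, 0.5, 1.0, -1.0
    u = sample_bridge(ncl, phi, rng)
    cl = np.repeat(np.arange(ncl), m)
    x = rng.integers(0, 2, ncl * m)
    y = (rng.random(ncl * m) < expit(u[cl] + w0 + b * x)).astype(int)
    fit = sm.Logit(y, sm.add_constant(x.astype(float))).fit(disp=0)
    assert fit.params[1] == pytest.approx(phi * b, abs=3 * fit.bse[1] + 0.02)
    assert fit.params[0] == pytest.approx(phi * w0, abs=3 * fit.bse[0] + 0.02)


def test_univariate_model_validates_inputs():
    y = np.array([0, 1, 2, 0])
    cl = np.array([0, 0, 0, 0])
    with pytest.raises(ValueError, match="two clusters"):
        BridgeMultinomial(np.ones((4, 0)), y, cl, 1)
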