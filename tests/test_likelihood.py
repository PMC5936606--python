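"""Category probabilities, design coding, and the adaptive-quadrature
marginal likelihood (against factorisation, additivity and MC oracles)."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from bridgejoint.bridge import bridge_icdf_normal
from bridgejoint.design import ModelSpec, build_design
from bridgejoint.likelihood import (JointLikelihood, QuadratureGrid,
                                    UnivariateLikelihood, category_probs,
                                    cluster_loglik, total_loglik)
from bridgejoint.params import ParameterVector

from conftest import binary_spec, simulate_joint


class TestCategoryProbs:
    def test_uniform_at_zero(self):
        np.testing.assert_allclose(category_probs([0.0, 0.0], 0.0),
                                   [1 / 3, 1 / 3, 1 / 3], rtol=1e-12)

    def test_reference_limit(self):
        p = category_probs([-50.0, -50.0], 0.0)
        assert abs(p[0] - 1.0) < 1e-20

    def test_hand_softmax(self):
        p = category_probs([np.log(2.0), 0.0], 0.0)
        np.testing.assert_allclose(p, [0.25, 0.5, 0.25], rtol=1e-12)

    def test_no_nan_for_extreme_inputs(self):
        p = category_probs([800.0, -800.0], 100.0)
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)


class TestBuildDesign:
    def frame(self):
        return pd.DataFrame({
            "hospital": ["A", "A", "B", "B"],
            "preeclampsia": ["Yes", "No", "No", "No"],
            "infant_sex": ["Male", "Female", "Male", "Female"],
            "gestational_age": ["preterm", "term", "term", "postterm"],
            "birth_weight": ["LBW", "normal", "macrosomia", "normal"],
        })

    def spec(self):
        return ModelSpec(predictors1=["preeclampsia"], predictors2=["infant_sex"])

    def test_binary_coding_against_reference_levels(self):
        d = build_design(self.frame(), self.spec())
        np.testing.assert_array_equal(d.X1[:, 0], [1, 0, 0, 0])
        np.testing.assert_array_equal(d.X2[:, 0], [1, 0, 1, 0])
        np.testing.assert_array_equal(d.y1, [1, 0, 0, 2])
        np.testing.assert_array_equal(d.y2, [1, 0, 2, 0])

    def test_missing_rows_dropped_with_count(self):
        df = self.frame()
        df.loc[1, "preeclampsia"] = None
        d = build_design(df, self.spec())
        assert d.n_dropped == 1 and d.n_obs == 3

    def test_unknown_label_names_row_and_column(self):
        df = self.frame()
        df.loc[2, "preeclampsia"] = "maybe"
        with pytest.raises(ValueError, match="preeclampsia"):
            build_design(df, self.spec())

    def test_all_missing_column_is_an_error(self):
        df = self.frame()
        df["preeclampsia"] = None
        with pytest.raises(ValueError, match="entirely missing"):
            build_design(df, self.spec())


def _loner_design(phi_degenerate=False):
    """Two one-row clusters with zero linear predictors."""
    df = pd.DataFrame({
        "hospital": ["A", "B"],
        "x": [0, 0],
        "gestational_age": ["term", "term"],
        "birth_weight": ["normal", "normal"],
    })
    return build_design(df, binary_spec())


def test_cluster_loglik_degenerate_intercepts():
    """phi -> 1 kills the random effects; a single row with flat categories
    contributes log(1/3) per outcome."""
    design = _loner_design()
    one = design.subset(design.cluster_codes == 0)
    params = ParameterVector([0.0, 0.0], [[0.0], [0.0]], [0.0, 0.0],
                             [[0.0], [0.0]], 1 - 1e-7, 1 - 1e-7, 0.0)
    val = cluster_loglik(one, params, 31)
    assert val == pytest.approx(2 * np.log(1 / 3), abs=1e-3)
    with pytest.raises(ValueError):
        cluster_loglik(design, params, 31)  # two clusters


def test_total_loglik_additive_over_clusters(small_design):
    design, truth = small_design
    total = total_loglik(design, truth, 15)
    parts = sum(cluster_loglik(design.subset(design.cluster_codes == c), truth, 15)
                for c in range(design.n_clusters))
    assert total == pytest.approx(parts, abs=1e-8)


def test_duplicating_clusters_doubles_loglik(small_cohort):
    df, truth, spec = small_cohort
    dup = df.copy()
    dup["hospital"] = dup["hospital"].astype(str) + "_copy"
    both = pd.concat([df.assign(hospital=df["hospital"].astype(str)), dup],
                     ignore_index=True)
    single = total_loglik(build_design(df, spec), truth, 15)
    double = total_loglik(build_design(both, spec), truth, 15)
    assert double == pytest.approx(2 * single, rel=1e-10)


def test_rho_zero_factorizes_into_univariate_quadratures(small_design):
    design, truth = small_design
    params = truth.copy(rho=0.0)
    joint = total_loglik(design, params, 21)
    lik1 = UnivariateLikelihood(design.X1, design.y1, design.cluster_codes,
                                design.n_clusters, 21)
    lik2 = UnivariateLikelihood(design.X2, design.y2, design.cluster_codes,
                                design.n_clusters, 21)
    separate = (lik1.loglik(params.omega, params.alpha, params.phi1)
                + lik2.loglik(params.theta, params.beta, params.phi2))
    assert joint == pytest.approx(separate, abs=1e-8)


def test_quadrature_node_convergence(small_design):
    """Default-grid accuracy: successive refinements agree to < 1e-6/obs."""
    design, truth = small_design
    l31 = total_loglik(design, truth, 31)
    l41 = total_loglik(design, truth, 41)
    assert abs(l31 - l41) / design.n_obs < 1e-6


def test_trapezoid_and_hermite_rules_agree(small_design):
    """Two independent node constructions converge to the same integral."""
    design, truth = small_design
    trap = total_loglik(design, truth, QuadratureGrid(61, "trapezoid"))
    herm = total_loglik(design, truth, QuadratureGrid(61, "hermite"))
    assert trap == pytest.approx(herm, abs=5e-5)


def test_copula_symmetry_under_outcome_swap(small_design):
    design, truth = small_design
    swapped = type(design)(design.X2, design.X1, design.y2, design.y1,
                           design.cluster_codes, design.cluster_labels,
                           design.names2, design.names1, design.spec)
    a = total_loglik(design, truth, 31)
    b = total_loglik(swapped, truth.swapped(), 31)
    assert a == pytest.approx(b, rel=1e-9, abs=1e-5)


def test_likelihood_peaks_near_generating_slope():
    df, truth, spec = simulate_joint(21, n_clusters=40, cluster_size=80)
    design = build_design(df, spec)
    at_truth = total_loglik(design, truth, 15)
    for delta in (-0.5, 0.5):
        off = truth.copy()
        off.alpha = truth.alpha + np.array([[delta], [0.0]])
        assert total_loglik(design, off, 15) < at_truth


def test_cluster_loglik_matches_monte_carlo(small_design):
    """Plain MC integration over copula draws (2e5) reproduces the adaptive
    quadrature value within 3 MC standard errors on small clusters."""
    design, truth = small_design
    rng = np.random.default_rng(123)
    n = 200_000
    z = rng.standard_normal((n, 2))
    w = truth.rho * z[:, 0] + np.sqrt(1 - truth.rho**2) * z[:, 1]
    u1 = bridge_icdf_normal(z[:, 0], truth.phi1)
    u2 = bridge_icdf_normal(w, truth.phi2)
    for c in range(2):
        sub = design.subset(design.cluster_codes == c)
        keep = rng.choice(sub.n_obs, size=min(6, sub.n_obs), replace=False)
        tiny = sub.subset(np.isin(np.arange(sub.n_obs), keep))
        quad = cluster_loglik(tiny, truth, 41)
        lp = np.zeros(n)
        for X, thr, slopes, y, u in [
                (tiny.X1, truth.omega, truth.alpha, tiny.y1, u1),
                (tiny.X2, truth.theta, truth.beta, tiny.y2, u2)]:
            eta = X @ slopes.T + thr
            probs = category_probs(eta[None, :, :], u[:, None])
            lp += np.log(np.take_along_axis(
                probs, y[None, :, None], axis=2)[:, :, 0]).sum(axis=1)
        mc = logsumexp(lp) - np.log(n)
        like = np.exp(lp)
        se = like.std(ddof=1) / np.sqrt(n)
        assert abs(np.exp(quad) - like.mean()) < 3 * se, (quad, mc)


def test_empty_dataset_rejected():
    with pytest.raises(ValueError):
        UnivariateLikelihood(np.empty((0, 1)), np.empty(0, dtype=int),
                             np.empty(0, dtype=int), 0)
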