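"""The synthetic cohort generator: covariate marginals, outcome calibration,
planted effects, and the simulate -> fit round trip."""

import numpy as np
import pandas as pd
import pytest

from bridgejoint.bridge import bridge_variance
from bridgejoint.design import ModelSpec, build_design
from bridgejoint.model import fit_joint
from bridgejoint.params import ParameterVector
from bridgejoint.simulate import (TARGET_PREVALENCES, CohortConfig,
                                  calibrate_thresholds, default_truth,
                                  generate_covariates, generate_outcomes,
                                  paper_like_cohort, read_cohort, write_cohort)


@pytest.fixture(scope="module")
def default_cohort():
    return paper_like_cohort(seed=5)


def test_covariate_marginals_match_reported_summaries():
    cov = generate_covariates(CohortConfig(seed=2))
    n = len(cov)
    assert n == 4415
    assert abs(cov.mother_age.mean() - 29.18) < 3 * 5.35 / np.sqrt(n)
    mp = (cov.multiple_pregnancy == "Yes").mean()
    target = 62 / 4415
    assert abs(mp - target) < 3 * np.sqrt(target * (1 - target) / n)
    pe = (cov.preeclampsia == "Yes").mean()
    assert abs(pe - 0.053) < 3 * np.sqrt(0.053 * 0.947 / n)


def test_generation_is_a_pure_function_of_seed():
    a = generate_covariates(CohortConfig(seed=11))
    b = generate_covariates(CohortConfig(seed=11))
    pd.testing.assert_frame_equal(a, b)
    c = generate_covariates(CohortConfig(seed=12))
    assert not a.equals(c)


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(n_clusters=0)
    with pytest.raises(ValueError):
        CohortConfig(rho=1.5)
    with pytest.raises(ValueError):
        CohortConfig(covariates={"bad": ("binary", 1.4)})
    with pytest.raises(ValueError):
        CohortConfig(covariates={"bad": ("normal", 0.0, -1.0)})


def test_null_slope_thresholds_reproduce_printed_prevalences():
    """With all slopes zero, thresholds calibrated through the Bridge
    marginalization identity must reproduce the published prevalences up to
    design-based simulation noise (binomial + between-hospital)."""
    # many clusters: the 3-SE normal band for the mean over clusters is
    # only trustworthy once the heavy-tailed cluster effects average out
    cfg = CohortConfig(seed=8, n_clusters=300, total_n=30_000)
    spec = cfg.spec
    zero1 = np.zeros((1, 2))  # no offsets
    omega = calibrate_thresholds(zero1, cfg.phi1,
                                 TARGET_PREVALENCES["gestational_age"])
    theta = calibrate_thresholds(zero1, cfg.phi2,
                                 TARGET_PREVALENCES["birth_weight"])
    truth = ParameterVector(omega, np.zeros((2, len(spec.predictors1))),
                            theta, np.zeros((2, len(spec.predictors2))),
                            cfg.phi1, cfg.phi2, cfg.rho,
                            names1=spec.predictors1, names2=spec.predictors2)
    cov = generate_covariates(cfg)
    sim = generate_outcomes(cov, truth, spec, seed=80)
    n = len(sim)
    sizes = sim.groupby("hospital").size().to_numpy()
    w2 = float(((sizes / n) ** 2).sum())  # design effect of unequal clusters

    # exact between-cluster variance of the category probabilities under the
    # Bridge law (heavy-tailed: a delta approximation is far too small)
    from bridgejoint.bridge import bridge_icdf_normal
    from bridgejoint.likelihood import category_probs
    from scipy.stats import norm as normal

    z = np.linspace(-8, 8, 4001)
    wz = normal.pdf(z) * (z[1] - z[0])
    for outcome, cats, thr, phi, targets in [
            (spec.outcome1, spec.categories1, omega, cfg.phi1,
             TARGET_PREVALENCES["gestational_age"]),
            (spec.outcome2, spec.categories2, theta, cfg.phi2,
             TARGET_PREVALENCES["birth_weight"])]:
        u = bridge_icdf_normal(z, phi)
        pu = category_probs(np.broadcast_to(thr, (z.size, 2)), u)  # (K, 3)
        mean_p = (pu * wz[:, None]).sum(axis=0)
        var_b = (pu**2 * wz[:, None]).sum(axis=0) - mean_p**2
        obs = sim[outcome].value_counts(normalize=True)
        for k, (cat, p) in enumerate(zip(cats, targets)):
            se = np.sqrt(p * (1 - p) / n + var_b[k] * w2)
            assert abs(obs.get(cat, 0.0) - p) < 3 * se, (outcome, cat, se)


def test_planted_multiple_pregnancy_effect_direction(default_cohort):
    cohort, _ = default_cohort
    rate = cohort.groupby("multiple_pregnancy")["gestational_age"].apply(
        lambda s: (s == "preterm").mean())
    assert rate["Yes"] > 5 * rate["No"]


def test_outcome_association_strengthens_with_rho():
    def cluster_assoc(rho, seed=44):
        cfg = CohortConfig(seed=seed, n_clusters=60, total_n=6000, rho=rho,
                           phi1=0.8, phi2=0.8)
        cov = generate_covariates(cfg)
        truth = default_truth(cfg, cov)
        sim = generate_outcomes(cov, truth, cfg.spec, seed=seed + 1)
        by = sim.groupby("hospital").agg(
            pre=("gestational_age", lambda s: (s == "preterm").mean()),
            lbw=("birth_weight", lambda s: (s == "LBW").mean()))
        return np.corrcoef(by.pre, by.lbw)[0, 1]

    assert cluster_assoc(0.9) > cluster_assoc(0.0)


def test_paper_like_cohort_satisfies_dataset_invariants(default_cohort):
    cohort, truth = default_cohort
    spec = CohortConfig().spec
    design = build_design(cohort, spec)
    assert design.n_dropped == 0
    assert design.n_clusters == 30
    assert np.bincount(design.cluster_codes).min() >= 1
    preterm_pct = 100 * (cohort.gestational_age == "preterm").mean()
    assert 3.0 <= preterm_pct <= 8.0
    assert truth.p1 == len(spec.predictors1)


def test_cohort_csv_roundtrip_records_seed(tmp_path):
    cohort, _ = paper_like_cohort(seed=3, n_clusters=5, total_n=200)
    path = tmp_path / "cohort.csv"
    write_cohort(cohort, path, seed=3)
    assert path.read_text().startswith("# seed=3\n")
    back = read_cohort(path)
    pd.testing.assert_frame_equal(back, cohort)


def test_truth_dimension_mismatch_is_an_error(default_cohort):
    cohort, truth = default_cohort
    bad_spec = ModelSpec(predictors1=["mother_age"], predictors2=["bmi"])
    with pytest.raises(ValueError, match="dimensions"):
        generate_outcomes(cohort, truth, bad_spec, seed=0)


def test_round_trip_recovery_of_planted_parameters():
    """Simulate a binary-predictor cohort at the generator's default random
    effect law and refit: every slope must land within 3 Wald SEs of its
    planted value and the random-effect law must be recovered."""
    spec = ModelSpec(
        predictors1=["preeclampsia", "art", "multiple_pregnancy"],
        predictors2=["stillbirth_history", "multiple_pregnancy",
                     "preeclampsia", "infant_sex"])
    cfg = CohortConfig(seed=17, n_clusters=50, total_n=6_000, spec=spec)
    cov = generate_covariates(cfg)
    truth = default_truth(cfg, cov)
    cohort = generate_outcomes(cov, truth, spec, seed=18)
    fit = fit_joint(cohort, spec, nodes=25)
    assert fit.converged
    tab = fit.or_table()
    planted = {("gestational_age", 0): truth.alpha, ("birth_weight", 0): truth.beta}
    for (outcome, slopes, names) in [
            ("gestational_age", truth.alpha, spec.predictors1),
            ("birth_weight", truth.beta, spec.predictors2)]:
        block = tab[tab.outcome == outcome]
        contrasts = block.contrast.unique()
        for ci, contrast in enumerate(contrasts):
            for j, name in enumerate(names):
                row = block[(block.contrast == contrast)
                            & (block.predictor == name)].iloc[0]
                if not np.isfinite(row.se):
                    continue  # boundary contrast with no events
                assert abs(row.coef - slopes[ci, j]) < 3 * row.se + 0.05, \
                    (outcome, contrast, name)
    assert abs(fit.params.phi1 - cfg.phi1) < 0.1
    assert abs(fit.params.phi2 - cfg.phi2) < 0.1
    assert abs(fit.params.rho - cfg.rho) < 0.35
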