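"""Synthetic clustered cohort generator.

The raw cohort behind this analysis is not deposited, so the package ships a
generator that reproduces its statistical structure: mothers nested in
hospitals, covariate marginals matching the published summary tables, and
the two 3-category outcomes drawn from the joint baseline-category logit
model with correlated Bridge random intercepts.

Default conditions
------------------
* 30 hospitals with lognormally dispersed sizes totalling 4415 mothers (the
  number of hospitals is not published; tens of university-supervised
  centres is the plausible order of magnitude).
* Covariate marginals from the published tables: e.g. mother's age
  ~ Normal(29.18, 5.35) truncated to [15, 50], preeclampsia prevalence
  0.053, ART 0.075, multiple pregnancy 0.014.
* Planted effect sizes equal to the published adjusted odds ratios
  (e.g. preeclampsia OR 4.14 on preterm, multiple pregnancy OR 18.04).
* Bridge scales phi1 = phi2 = 0.95 (moderate between-hospital heterogeneity,
  latent ICC ~ 0.10) and copula correlation rho = 0.6.
* Outcome thresholds are *calibrated*, not tuned: they solve the marginal
  prevalence equations (averaging the category probabilities over the
  covariate sample and the Bridge law) for the published prevalences
  5.5/94.0/0.5% and 4.8/92.4/2.8%.

All draws are a pure function of the config and its integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bridge import BivariateBridgeParams, bridge_icdf_normal, sample_bivariate_bridge
from .design import DEFAULT_BINARY_LEVELS, ModelSpec, default_spec
from .likelihood import category_probs
from .params import ParameterVector

__all__ = ["CohortConfig", "generate_covariates", "generate_outcomes",
           "paper_like_cohort", "calibrate_thresholds", "default_truth",
           "write_cohort", "read_cohort", "DEFAULT_COVARIATES",
           "PLANTED_ODDS_RATIOS", "TARGET_PREVALENCES"]

#: covariate marginals emulating the published cohort summaries
DEFAULT_COVARIATES: dict[str, tuple] = {
    "mother_age": ("truncnorm", 29.18, 5.35, 15.0, 50.0),
    "father_age": ("truncnorm", 33.50, 5.80, 18.0, 70.0),
    "ses": ("normal", 0.0, 2.0),
    "bmi": ("truncnorm", 25.0, 5.0, 15.0, 45.0),
    "parity": ("binary", 0.511),
    "mother_education": ("binary", 0.327),
    "father_education": ("binary", 0.320),
    "occupation": ("binary", 0.122),
    "pregnancy_type": ("binary", 0.193),
    "abortion_history": ("binary", 0.193),
    "stillbirth_history": ("binary", 0.0174),
    "preeclampsia": ("binary", 0.053),
    "art": ("binary", 0.075),
    "multiple_pregnancy": ("binary", 0.014),
    "infant_sex": ("binary", 0.507),
}

#: planted per-category odds ratios (non-reference category -> {predictor: OR});
#: values follow the published adjusted estimates, with the two garbled
#: postterm entries for preeclampsia/ART replaced by the null value 1.0
PLANTED_ODDS_RATIOS = {
    "gestational_age": {
        "preterm": {"mother_age": 1.04, "ses": 0.97, "mother_education": 1.29,
                    "preeclampsia": 4.14, "art": 2.47, "multiple_pregnancy": 18.04},
        "postterm": {"mother_age": 0.92, "ses": 0.53, "mother_education": 0.82,
                     "preeclampsia": 1.0, "art": 1.0, "multiple_pregnancy": 0.61},
    },
    "birth_weight": {
        "LBW": {"mother_age": 1.01, "bmi": 1.01, "mother_education": 1.15,
                "stillbirth_history": 2.17, "multiple_pregnancy": 17.35,
                "preeclampsia": 3.36, "infant_sex": 0.87},
        "macrosomia": {"mother_age": 1.01, "bmi": 1.02, "mother_education": 1.10,
                       "stillbirth_history": 2.47, "multiple_pregnancy": 0.72,
                       "preeclampsia": 1.4, "infant_sex": 1.78},
    },
}

#: marginal category targets (reference first), from the printed group sizes
TARGET_PREVALENCES = {
    "gestational_age": np.array([4149, 244, 22]) / 4415.0,
    "birth_weight": np.array([4078, 213, 124]) / 4415.0,
}


@dataclass
class CohortConfig:
    n_clusters: int = 30
    total_n: int = 4415
    seed: int = 0
    phi1: float = 0.95
    phi2: float = 0.95
    rho: float = 0.6
    spec: ModelSpec = field(default_factory=default_spec)
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    size_dispersion: float = 0.5  # sd of log cluster-size weights

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.total_n < self.n_clusters:
            raise ValueError("need n_clusters >= 1 and total_n >= n_clusters")
        BivariateBridgeParams(self.phi1, self.phi2, self.rho)
        for name, spec in self.covariates.items():
            kind = spec[0]
            if kind == "binary":
                if not 0.0 <= spec[1] <= 1.0:
                    raise ValueError(f"{name}: prevalence must be in [0, 1]")
            elif kind in ("normal", "truncnorm"):
                if spec[2] <= 0:
                    raise ValueError(f"{name}: scale must be positive")
            else:
                raise ValueError(f"{name}: unknown covariate kind {kind!r}")

    def replace(self, **changes) -> "CohortConfig":
        return replace(self, **changes)


def _draw_covariate(spec, n: int, rng: np.random.Generator, name: str):
    kind = spec[0]
    if kind == "normal":
        return rng.normal(spec[1], spec[2], n)
    if kind == "truncnorm":
        _, mu, sd, lo, hi = spec
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
    # binary with labels from the standard coding table
    ref, event = DEFAULT_BINARY_LEVELS.get(name, ("No", "Yes"))
    return np.where(rng.random(n) < spec[1], event, ref)


def generate_covariates(config: CohortConfig) -> pd.DataFrame:
    """Hospital ids and covariates; one row per mother, independent columns."""
    rng = np.random.default_rng(config.seed)
    weights = rng.lognormal(0.0, config.size_dispersion, config.n_clusters)
    sizes = rng.multinomial(config.total_n - config.n_clusters,
                            weights / weights.sum()) + 1
    hospital = np.repeat([f"H{i + 1:02d}" for i in range(config.n_clusters)], sizes)
    n = hospital.size
    data = {"hospital": hospital}
    for name, spec in config.covariates.items():
        data[name] = _draw_covariate(spec, n, rng, name)
    return pd.DataFrame(data)


def _code_columns(df: pd.DataFrame, names) -> np.ndarray:
    cols = []
    for name in names:
        col = df[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            ref, event = DEFAULT_BINARY_LEVELS[name]
            cols.append((col == event).to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def calibrate_thresholds(offsets: np.ndarray, phi: float,
                         target: np.ndarray, nodes: int = 41) -> np.ndarray:
    """Thresholds solving the marginal prevalence equations.

    Finds (t1, t2) such that averaging the category probabilities over the
    covariate offsets and the Bridge random-intercept law reproduces the
    target marginal prevalences.  The starting point uses the Bridge
    logit-marginalization identity on each binary collapse.
    """
    target = np.asarray(target, dtype=float)
    offsets = np.asarray(offsets, dtype=float).reshape(-1, 2)
    x, w = np.polynomial.hermite.hermgauss(nodes)
    u = bridge_icdf_normal(np.sqrt(2.0) * x, phi)
    w = w / np.sqrt(np.pi)

    def marginal(thr):
        # broadcast: offsets (n,1,2) + thresholds, intercept nodes u (1,K)
        probs = category_probs(offsets[:, None, :] + thr[None, None, :],
                               u[None, :])
        return (probs * w[None, :, None]).sum(axis=1).mean(axis=0)

    start = (np.log(target[1:] / target[0]) / phi) - offsets.mean(axis=0)
    sol = optimize.root(lambda t: marginal(t)[1:] - target[1:], start,
                        method="hybr", tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"threshold calibration failed: {sol.message}")
    return sol.x


def default_truth(config: CohortConfig, covariates: pd.DataFrame) -> ParameterVector:
    """The generator's planted parameter vector, thresholds calibrated
    against the given covariate sample."""
    spec = config.spec

    def slopes(outcome_key, names):
        block = PLANTED_ODDS_RATIOS[outcome_key]
        cats = list(block.keys())
        return np.array([[np.log(block[c].get(nm, 1.0)) for nm in names]
                         for c in cats])

    alpha = slopes("gestational_age", spec.predictors1)
    beta = slopes("birth_weight", spec.predictors2)
    X1 = _code_columns(covariates, spec.predictors1)
    X2 = _code_columns(covariates, spec.predictors2)
    omega = calibrate_thresholds(X1 @ alpha.T, config.phi1,
                                 TARGET_PREVALENCES["gestational_age"])
    theta = calibrate_thresholds(X2 @ beta.T, config.phi2,
                                 TARGET_PREVALENCES["birth_weight"])
    return ParameterVector(omega, alpha, theta, beta, config.phi1, config.phi2,
                           config.rho, names1=list(spec.predictors1),
                           names2=list(spec.predictors2))


def generate_outcomes(covariates: pd.DataFrame, truth: ParameterVector,
                      spec: ModelSpec, seed: int) -> pd.DataFrame:
    """Draw the two outcomes given covariates and the planted parameters.

    Per hospital a (u1, u2) pair is drawn from the Gaussian-copula bivariate
    Bridge; per mother the category probabilities follow the two
    baseline-category logits and a single categorical draw per outcome.
    """
    X1 = _code_columns(covariates, spec.predictors1)
    X2 = _code_columns(covariates, spec.predictors2)
    if X1.shape[1] != truth.p1 or X2.shape[1] != truth.p2:
        raise ValueError("truth dimensions do not match the covariate columns")
    labels, codes = np.unique(covariates[spec.cluster].to_numpy(), return_inverse=True)
    rng = np.random.default_rng(seed)
    uu = sample_bivariate_bridge(labels.size, truth.bridge, rng)
    out = covariates.copy()
    for (X, thr, slopes, cats, name, u) in [
            (X1, truth.omega, truth.alpha, spec.categories1, spec.outcome1, uu[:, 0]),
            (X2, truth.theta, truth.beta, spec.categories2, spec.outcome2, uu[:, 1])]:
        eta = X @ slopes.T + thr
        probs = category_probs(eta, u[codes])
        draws = (rng.random(len(out))[:, None] > probs.cumsum(axis=1)).sum(axis=1)
        out[name] = np.asarray(cats)[draws]
    return out


def paper_like_cohort(seed: int, n_clusters: int = 30, total_n: int = 4415,
                      config: CohortConfig | None = None):
    """One-call end-to-end demo cohort.

    Returns ``(cohort, truth)``: a table whose descriptive surface is
    comparable to the published cohort, and the planted parameter vector.
    """
    config = (config or CohortConfig()).replace(
        seed=seed, n_clusters=n_clusters, total_n=total_n)
    covariates = generate_covariates(config)
    truth = default_truth(config, covariates)
    cohort = generate_outcomes(covariates, truth, config.spec, seed=config.seed + 1)
    return cohort, truth


def write_cohort(df: pd.DataFrame, path, seed=None) -> None:
    """CSV with the generating seed recorded on a header comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
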