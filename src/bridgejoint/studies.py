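"""Simulation studies validating the estimator.

These are the package's built-in method-validation procedures: a Wald-CI
coverage (parameter recovery) study, a type-I-error calibration study of the
screening stage, a quadrature-vs-Monte-Carlo likelihood check, and the
numerical verification of the Bridge marginalization identity.  Each is a
pure function of its integer seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import expit
from scipy.stats import chi2

from .bridge import bridge_icdf_normal, bridge_pdf, marginalize_logit, sample_bridge
from .design import ModelSpec, build_design
from .likelihood import JointLikelihood, category_probs
from .model import BridgeMultinomial, JointBridgeMultinomial
from .params import ParameterVector

__all__ = ["marginalization_max_error", "mc_likelihood_check",
           "recovery_study", "screening_null_study"]


def marginalization_max_error(etas=None, phis=None) -> float:
    """Max |int expit(u+eta) f(u;phi) du - expit(phi eta)| over a grid."""
    etas = np.linspace(-4.0, 4.0, 17) if etas is None else np.asarray(etas)
    phis = np.arange(0.2, 0.95, 0.1) if phis is None else np.asarray(phis)
    worst = 0.0
    for phi in phis:
        for eta in etas:
            val, _ = integrate.quad(
                lambda u: expit(u + eta) * bridge_pdf(u, phi),
                -np.inf, np.inf, limit=300)
            worst = max(worst, abs(val - float(marginalize_logit(eta, phi))))
    return worst


def _binary_spec() -> ModelSpec:
    return ModelSpec(predictors1=["x"], predictors2=["x"])


def _recovery_truth() -> ParameterVector:
    return ParameterVector([-2.0, -2.5], [[np.log(4.0)], [0.0]],
                           [-2.0, -2.5], [[0.0], [0.0]], 0.6, 0.6, 0.5,
                           names1=["x"], names2=["x"])


def _simulate_binary_cohort(truth: ParameterVector, n_clusters: int,
                            cluster_size: int, seed: int) -> pd.DataFrame:
    from .simulate import generate_outcomes

    rng = np.random.default_rng(seed)
    n = n_clusters * cluster_size
    cov = pd.DataFrame({"hospital": np.repeat(np.arange(n_clusters), cluster_size),
                        "x": rng.integers(0, 2, n)})
    return generate_outcomes(cov, truth, _binary_spec(), seed=seed + 1)


def recovery_study(n_replicates: int = 100, seed: int = 0,
                   n_clusters: int = 50, cluster_size: int = 100,
                   nodes: int = 15) -> dict:
    """Wald-CI coverage of the planted preterm log-OR (ln 4) for a binary
    predictor across replicate joint fits.

    Returns coverage counts plus the mean estimate and convergence record.
    """
    truth = _recovery_truth()
    target = float(truth.alpha[0, 0])
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    covered = 0
    n_converged = 0
    coefs = []
    for rep_seed in sub_seeds:
        df = _simulate_binary_cohort(truth, n_clusters, cluster_size,
                                     int(rep_seed))
        fit = JointBridgeMultinomial.from_dataframe(df, _binary_spec(),
                                                    nodes=nodes).fit()
        tab = fit.or_table()
        row = tab[(tab.outcome == "gestational_age")
                  & (tab.contrast == "preterm vs term")].iloc[0]
        n_converged += fit.converged
        coefs.append(row.coef)
        if np.log(row.ci_low) <= target <= np.log(row.ci_high):
            covered += 1
    return {"covered": covered, "n_replicates": n_replicates,
            "coverage": covered / n_replicates,
            "mean_coef": float(np.mean(coefs)), "target_coef": target,
            "n_converged": n_converged}


def screening_null_study(n_sims: int = 200, seed: int = 0,
                         n_clusters: int = 30, cluster_size: int = 50,
                         phi: float = 0.6, threshold: float = 0.20,
                         nodes: int = 21) -> dict:
    """Selection rate of a pure-noise binary predictor for one outcome.

    The 2-df likelihood-ratio screening p-value should be uniform under the
    null, so the selection rate at the entry threshold estimates it.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_sims)
    thr = np.array([-2.3, -2.8])
    hits = 0
    n = n_clusters * cluster_size
    cl = np.repeat(np.arange(n_clusters), cluster_size)
    for s in sub_seeds:
        r = np.random.default_rng(int(s))
        u = sample_bridge(n_clusters, phi, r)
        x = r.integers(0, 2, n)
        probs = category_probs(np.broadcast_to(thr, (n, 2)), u[cl])
        y = (r.random(n)[:, None] > probs.cumsum(axis=1)).sum(axis=1)
        null = BridgeMultinomial(np.empty((n, 0)), y, cl, n_clusters,
                                 nodes=nodes).fit(compute_cov=False)
        alt = BridgeMultinomial(x[:, None], y, cl, n_clusters,
                                nodes=nodes).fit(compute_cov=False)
        lrt = max(0.0, 2.0 * (alt.loglik - null.loglik))
        hits += bool(chi2.sf(lrt, 2) < threshold)
    return {"hits": hits, "n_sims": n_sims, "rate": hits / n_sims,
            "threshold": threshold}


def mc_likelihood_check(seed: int = 0, n_draws: int = 1_000_000,
                        n_clusters: int = 5, nodes: int = 41) -> list[dict]:
    """Adaptive-quadrature cluster likelihoods against plain Monte-Carlo
    integration over Gaussian-copula draws, on small random clusters.

    Returns one record per cluster with the quadrature likelihood, the MC
    estimate and its standard error (all on the likelihood scale).
    """
    rng = np.random.default_rng(seed)
    truth = ParameterVector([-1.2, -1.8], [[0.8, 0.05], [-0.3, 0.02]],
                            [-1.0, -2.0], [[0.5, -0.04], [0.2, 0.03]],
                            0.7, 0.55, 0.4, names1=["b", "c"], names2=["b", "c"])
    sizes = rng.integers(3, 9, size=n_clusters)
    rows = []
    for i, size in enumerate(sizes):
        b = rng.integers(0, 2, size).astype(float)
        c = rng.normal(0, 1, size)
        X = np.column_stack([b, c])
        u_true = rng.normal(0, 1, 2)
        eta1 = X @ truth.alpha.T + truth.omega
        eta2 = X @ truth.beta.T + truth.theta
        y1 = (rng.random(size)[:, None]
              > category_probs(eta1, np.full(size, u_true[0])).cumsum(1)).sum(1)
        y2 = (rng.random(size)[:, None]
              > category_probs(eta2, np.full(size, u_true[1])).cumsum(1)).sum(1)
        rows.append(pd.DataFrame({
            "hospital": f"H{i}", "b": b, "c": c,
            "gestational_age": np.array(["term", "preterm", "postterm"])[y1],
            "birth_weight": np.array(["normal", "LBW", "macrosomia"])[y2]}))
    spec = ModelSpec(predictors1=["b", "c"], predictors2=["b", "c"])
    design = build_design(pd.concat(rows, ignore_index=True), spec)

    quad = JointLikelihood(design, nodes).cluster_logliks(truth)

    # Monte Carlo: shared copula draws, chunked over clusters
    z = rng.standard_normal((n_draws, 2))
    w = truth.rho * z[:, 0] + np.sqrt(1 - truth.rho**2) * z[:, 1]
    u1 = bridge_icdf_normal(z[:, 0], truth.phi1)
    u2 = bridge_icdf_normal(w, truth.phi2)
    out = []
    chunk = 200_000
    for i in range(design.n_clusters):
        sub = design.subset(design.cluster_codes == i)
        like = np.empty(n_draws)
        for lo in range(0, n_draws, chunk):
            hi = lo + chunk
            lp = np.zeros(hi - lo if hi <= n_draws else n_draws - lo)
            for X, thr, slopes, y, u in [
                    (sub.X1, truth.omega, truth.alpha, sub.y1, u1[lo:hi]),
                    (sub.X2, truth.theta, truth.beta, sub.y2, u2[lo:hi])]:
                eta = X @ slopes.T + thr
                probs = category_probs(eta[None, :, :], u[:, None])
                picked = np.take_along_axis(probs, y[None, :, None], axis=2)[:, :, 0]
                lp += np.log(picked).sum(axis=1)
            like[lo:lo + lp.size] = np.exp(lp)
        mc_mean = float(like.mean())
        mc_se = float(like.std(ddof=1) / np.sqrt(n_draws))
        out.append({"cluster": i, "n_rows": int(sub.n_obs),
                    "quad_likelihood": float(np.exp(quad[i])),
                    "mc_likelihood": mc_mean, "mc_se": mc_se})
    return out
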