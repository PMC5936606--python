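"""Model classes and maximum-likelihood fitting.

`JointBridgeMultinomial` is the joint two-outcome model; `BridgeMultinomial`
is the single-outcome analogue used for univariate screening.  Both follow
the Model/Results convention: build the model from data, call ``fit()``, and
work with the returned results object.

Estimation maximises the adaptive-quadrature marginal likelihood with
L-BFGS-B on an unconstrained parametrisation (``phi`` via inverse-logit,
``rho`` via tanh) and finite-difference gradients.  Standard errors come
from the observed information, a central-difference Hessian at the optimum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .design import DesignData, ModelSpec, build_design
from .likelihood import JointLikelihood, UnivariateLikelihood
from .params import ParameterVector
from .results import JointBridgeResults, UnivariateResults

__all__ = ["JointBridgeMultinomial", "BridgeMultinomial",
           "fit_joint", "fit_univariate"]


def _check_full_rank(X: np.ndarray, names, label: str) -> None:
    """Reject rank-deficient designs, naming the offending columns."""
    if X.shape[1] == 0:
        return
    const = [names[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0.0]
    if const:
        raise ValueError(f"{label}: constant (zero-variance) predictor columns {const}")
    Z = np.column_stack([np.ones(len(X)), X])
    s = np.linalg.svd(Z, compute_uv=False)
    if s[-1] < 1e-8 * s[0]:
        # point at the most collinear columns via the null-space vector
        _, _, vt = np.linalg.svd(Z)
        weights = np.abs(vt[-1][1:])
        bad = [names[j] for j in np.argsort(weights)[::-1][:2]]
        raise ValueError(f"{label}: design matrix is rank deficient; "
                         f"most collinear columns: {bad}")


def _fd_hessian(fun, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        fpp = fun(x + ei); fmm = fun(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (fun(x + ei + ej) - fun(x + ei - ej)
                                 - fun(x - ei + ej) + fun(x - ei - ej)) / (4 * h[i] * h[j])
    return H


def _maximize(neg, x0: np.ndarray, maxiter: int, n_starts: int, seed: int):
    """L-BFGS-B with optional jittered multi-start; returns the best result."""
    best = None
    rng = np.random.default_rng(seed)
    for s in range(max(1, n_starts)):
        xs = x0 if s == 0 else x0 + 0.1 * rng.standard_normal(x0.size)
        res = optimize.minimize(neg, xs, method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": 1e-11,
                                         "gtol": 1e-7, "maxcor": 25})
        if best is None or res.fun < best.fun:
            best = res
    return best


class JointBridgeMultinomial:
    """Joint multilevel baseline-category logit with correlated Bridge
    random intercepts for two 3-category outcomes on shared clusters."""

    def __init__(self, design: DesignData, nodes: int = 31):
        if design.n_clusters < 2:
            raise ValueError("need at least two clusters to identify the "
                             "random-intercept distribution")
        _check_full_rank(design.X1, design.names1, "outcome-1 sub-model")
        _check_full_rank(design.X2, design.names2, "outcome-2 sub-model")
        self.design = design
        self.nodes = nodes
        self._lik = JointLikelihood(design, nodes)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec,
                       nodes: int = 31) -> "JointBridgeMultinomial":
        return cls(build_design(df, spec), nodes=nodes)

    # -- likelihood ---------------------------------------------------------
    def loglike(self, params: ParameterVector) -> float:
        return self._lik.loglik(params)

    def loglike_flat(self, x: np.ndarray) -> float:
        return self.loglike(self._unpack(x))

    def _unpack(self, x: np.ndarray) -> ParameterVector:
        d = self.design
        return ParameterVector.from_unconstrained(
            x, d.X1.shape[1], d.X2.shape[1], d.names1, d.names2)

    def start_params(self, phi0: float = 0.7) -> ParameterVector:
        """Deterministic start: slopes zero, thresholds from marginal
        category frequencies deflated by the Bridge attenuation."""
        d = self.design
        def thr(y):
            counts = np.bincount(y, minlength=3).astype(float) + 0.5
            return np.log(counts[1:] / counts[0]) / phi0
        p1, p2 = d.X1.shape[1], d.X2.shape[1]
        return ParameterVector(thr(d.y1), np.zeros((2, p1)), thr(d.y2),
                               np.zeros((2, p2)), phi0, phi0, 0.0,
                               names1=d.names1, names2=d.names2)

    def fit(self, start: ParameterVector | None = None, maxiter: int = 500,
            n_starts: int = 1, seed: int = 0, fix_rho: float | None = None,
            compute_cov: bool = True) -> JointBridgeResults:
        """Maximise the marginal likelihood.

        ``fix_rho`` profiles the copula correlation at a fixed value
        (``fix_rho=0`` fits the two sub-models as independent).
        """
        d = self.design
        x0 = (start or self.start_params()).to_unconstrained()
        free = np.ones(x0.size, dtype=bool)
        if fix_rho is not None:
            x0[-1] = np.arctanh(fix_rho)
            free[-1] = False
        template = x0.copy()

        def embed(xf):
            x = template.copy()
            x[free] = xf
            return x

        def neg(xf):
            val = self.loglike_flat(embed(xf))
            return -val if np.isfinite(val) else 1e12

        res = _maximize(neg, x0[free], maxiter, n_starts, seed)
        xhat = embed(res.x)
        params = self._unpack(xhat)
        loglik = -res.fun

        cov = None
        if compute_cov:
            Hf = _fd_hessian(lambda xf: -neg(xf), res.x)
            try:
                cov_free = np.linalg.inv(-Hf)
            except np.linalg.LinAlgError:
                cov_free = np.linalg.pinv(-Hf)
            cov = np.full((x0.size, x0.size), np.nan)
            idx = np.where(free)[0]
            cov[np.ix_(idx, idx)] = cov_free

        diagnostics = {
            "optimizer_message": str(res.message),
            "n_iterations": int(res.nit),
            "n_function_evals": int(res.nfev),
            "grad_max_norm": float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
            "fixed_rho": fix_rho,
        }
        return JointBridgeResults(
            model=self, params=params, params_flat=xhat, cov_flat=cov,
            loglik=loglik, converged=bool(res.success),
            n_obs=d.n_obs, n_clusters=d.n_clusters, diagnostics=diagnostics)


class BridgeMultinomial:
    """Single-outcome multilevel baseline-category logit with one Bridge
    random intercept; the univariate-screening workhorse."""

    def __init__(self, X: np.ndarray, y: np.ndarray, cluster_codes: np.ndarray,
                 n_clusters: int, names=None, categories=None, nodes: int = 31):
        X = np.asarray(X, dtype=float).reshape(len(y), -1)
        self.names = list(names or [f"x{j}" for j in range(X.shape[1])])
        self.categories = tuple(categories or ("ref", "cat1", "cat2"))
        if n_clusters < 2:
            raise ValueError("need at least two clusters")
        _check_full_rank(X, self.names, "sub-model")
        self.X, self.y = X, np.asarray(y, dtype=np.int64)
        self.cluster_codes = np.asarray(cluster_codes, dtype=np.int64)
        self.n_clusters = n_clusters
        self.nodes = nodes
        self._lik = UnivariateLikelihood(X, self.y, self.cluster_codes,
                                         n_clusters, nodes)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def loglike_flat(self, x: np.ndarray) -> float:
        thr = x[:2]
        slopes = x[2:2 + 2 * self.p].reshape(2, self.p)
        phi = float(np.clip(expit(x[-1]), 1e-9, 1.0 - 1e-9))
        return self._lik.loglik(thr, slopes, phi)

    def start_flat(self, phi0: float = 0.7) -> np.ndarray:
        counts = np.bincount(self.y, minlength=3).astype(float) + 0.5
        thr = np.log(counts[1:] / counts[0]) / phi0
        return np.concatenate([thr, np.zeros(2 * self.p), [logit(phi0)]])

    def fit(self, maxiter: int = 500, n_starts: int = 1, seed: int = 0,
            compute_cov: bool = True) -> UnivariateResults:
        def neg(x):
            val = self.loglike_flat(x)
            return -val if np.isfinite(val) else 1e12

        res = _maximize(neg, self.start_flat(), maxiter, n_starts, seed)
        cov = None
        if compute_cov:
            H = _fd_hessian(lambda x: -neg(x), res.x)
            try:
                cov = np.linalg.inv(-H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(-H)
        return UnivariateResults(
            model=self, params_flat=res.x, cov_flat=cov, loglik=-res.fun,
            converged=bool(res.success), n_obs=self.y.size,
            n_clusters=self.n_clusters,
            diagnostics={"optimizer_message": str(res.message),
                         "n_iterations": int(res.nit)})


# -- functional wrappers ----------------------------------------------------

def fit_joint(data, spec: ModelSpec | None = None, nodes: int = 31,
              **options) -> JointBridgeResults:
    """Fit the joint model from a raw cohort table or a built design."""
    if isinstance(data, DesignData):
        model = JointBridgeMultinomial(data, nodes=nodes)
    else:
        if spec is None:
            raise ValueError("spec is required when fitting from a raw table")
        model = JointBridgeMultinomial.from_dataframe(data, spec, nodes=nodes)
    return model.fit(**options)


def fit_univariate(df: pd.DataFrame, predictor: str | None, outcome: str,
                   spec: ModelSpec, nodes: int = 31, **options) -> UnivariateResults:
    """Fit the single-predictor multilevel model for one outcome.

    ``predictor=None`` fits the intercept-only (null) model used as the
    likelihood-ratio baseline.
    """
    preds = [predictor] if predictor else []
    sub = spec.with_predictors(preds, preds)
    design = build_design(df, sub)
    if outcome in (1, spec.outcome1):
        X, y, cats = design.X1, design.y1, spec.categories1
    elif outcome in (2, spec.outcome2):
        X, y, cats = design.X2, design.y2, spec.categories2
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    model = BridgeMultinomial(X, y, design.cluster_codes, design.n_clusters,
                              names=preds, categories=cats, nodes=nodes)
    return model.fit(**options)
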