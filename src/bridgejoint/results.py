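"""Results objects: estimates, observed-information uncertainty, odds-ratio
tables with Wald confidence intervals, and text summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from scipy.stats import norm

__all__ = ["JointBridgeResults", "UnivariateResults", "wald_intervals"]


def _wald_rows(rows):
    df = pd.DataFrame(rows, columns=["outcome", "contrast", "predictor",
                                     "coef", "se", "OR", "ci_low", "ci_high", "p"])
    return df


def _wald_entry(b: float, se: float, level: float):
    """OR, CI by endpoint transformation, two-sided normal p-value."""
    if not np.isfinite(se) or se <= 0:
        return np.exp(b), np.nan, np.nan, np.nan
    q = norm.ppf(0.5 + level / 2.0)
    with np.errstate(over="ignore"):
        return (np.exp(b), np.exp(b - q * se), np.exp(b + q * se),
                2.0 * ndtr(-abs(b / se)))


@dataclass
class JointBridgeResults:
    """Fit of the joint two-outcome model."""

    model: object
    params: object                 # ParameterVector at the optimum
    params_flat: np.ndarray        # unconstrained coordinates
    cov_flat: np.ndarray | None    # covariance on the unconstrained scale
    loglik: float
    converged: bool
    n_obs: int
    n_clusters: int
    diagnostics: dict = field(default_factory=dict)

    # -- index bookkeeping on the flat vector -------------------------------
    def _slope_index(self, outcome: int, cat: int, j: int) -> int:
        p1, p2 = self.params.p1, self.params.p2
        if outcome == 1:
            return 2 + cat * p1 + j
        return 2 + 2 * p1 + 2 + cat * p2 + j

    def _threshold_index(self, outcome: int, cat: int) -> int:
        if outcome == 1:
            return cat
        return 2 + 2 * self.params.p1 + cat

    def bse_flat(self) -> np.ndarray:
        if self.cov_flat is None:
            return np.full(self.params_flat.size, np.nan)
        return np.sqrt(np.maximum(np.diag(self.cov_flat), 0.0))

    # -- odds-ratio table ----------------------------------------------------
    def or_table(self, level: float = 0.95) -> pd.DataFrame:
        """Per predictor and non-reference category: OR, CI, Wald p."""
        spec = self.model.design.spec
        se = self.bse_flat()
        rows = []
        blocks = [(1, spec.outcome1, spec.categories1, self.params.names1,
                   self.params.alpha),
                  (2, spec.outcome2, spec.categories2, self.params.names2,
                   self.params.beta)]
        for outcome, oname, cats, names, slopes in blocks:
            for cat in (0, 1):
                contrast = f"{cats[cat + 1]} vs {cats[0]}"
                for j, pred in enumerate(names):
                    b = slopes[cat, j]
                    s = se[self._slope_index(outcome, cat, j)]
                    orx, lo, hi, p = _wald_entry(b, s, level)
                    rows.append((oname, contrast, pred, b, s, orx, lo, hi, p))
        return _wald_rows(rows)

    def random_effect_table(self, level: float = 0.95) -> pd.DataFrame:
        """phi1, phi2, rho with delta-method CIs from the unconstrained scale."""
        se = self.bse_flat()
        k = self.params_flat.size
        q = norm.ppf(0.5 + level / 2.0)
        rows = []
        for name, value, idx, trans in [
                ("phi1", self.params.phi1, k - 3, expit),
                ("phi2", self.params.phi2, k - 2, expit),
                ("rho", self.params.rho, k - 1, np.tanh)]:
            x = self.params_flat[idx]
            s = se[idx]
            lo, hi = ((trans(x - q * s), trans(x + q * s))
                      if np.isfinite(s) else (np.nan, np.nan))
            rows.append((name, value, lo, hi))
        return pd.DataFrame(rows, columns=["parameter", "estimate",
                                           "ci_low", "ci_high"])

    def summary(self, level: float = 0.95) -> str:
        spec = self.model.design.spec
        lines = [
            "Joint multilevel baseline-category logit with Bridge random intercepts",
            "=" * 72,
            f"outcomes: {spec.outcome1} (ref {spec.ref1!r}), "
            f"{spec.outcome2} (ref {spec.ref2!r})",
            f"n_obs: {self.n_obs}    n_clusters: {self.n_clusters}    "
            f"log-likelihood: {self.loglik:.4f}",
            f"converged: {self.converged}",
            "",
            "Odds ratios (Wald, level {:.0%})".format(level),
            self.or_table(level).to_string(
                index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            "Random-intercept law (bivariate Bridge, Gaussian copula)",
            self.random_effect_table(level).to_string(
                index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


@dataclass
class UnivariateResults:
    """Fit of the single-outcome multilevel baseline-category model."""

    model: object
    params_flat: np.ndarray  # [thresholds(2), slopes(2p), logit(phi)]
    cov_flat: np.ndarray | None
    loglik: float
    converged: bool
    n_obs: int
    n_clusters: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def phi(self) -> float:
        return float(expit(self.params_flat[-1]))

    @property
    def slopes(self) -> np.ndarray:
        p = self.model.p
        return self.params_flat[2:2 + 2 * p].reshape(2, p)

    def bse_flat(self) -> np.ndarray:
        if self.cov_flat is None:
            return np.full(self.params_flat.size, np.nan)
        return np.sqrt(np.maximum(np.diag(self.cov_flat), 0.0))

    def or_table(self, level: float = 0.95) -> pd.DataFrame:
        cats = self.model.categories
        se = self.bse_flat()
        p = self.model.p
        rows = []
        for cat in (0, 1):
            contrast = f"{cats[cat + 1]} vs {cats[0]}"
            for j, pred in enumerate(self.model.names):
                b = self.slopes[cat, j]
                s = se[2 + cat * p + j]
                orx, lo, hi, pv = _wald_entry(b, s, level)
                rows.append(("outcome", contrast, pred, b, s, orx, lo, hi, pv))
        return _wald_rows(rows)


def wald_intervals(fit, level: float = 0.95) -> pd.DataFrame:
    """Odds-ratio table with Wald confidence intervals from a fitted model."""
    if not fit.converged:
        raise ValueError("Wald intervals require a converged fit; "
                         f"diagnostics: {fit.diagnostics}")
    return fit.or_table(level)
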