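"""Univariate variable-entry screening.

Each candidate predictor is tested in a single-predictor multilevel
baseline-category model per outcome; the predictor-level p-value is a 2-df
likelihood-ratio test (both non-reference contrasts jointly) against the
intercept-only model.  A predictor enters the joint model if its p-value is
below the threshold (default 0.20, a deliberately liberal entry rule) for
at least one outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelSpec
from .model import fit_univariate

logger = logging.getLogger("bridgejoint")

__all__ = ["ScreeningResult", "screen"]


@dataclass
class ScreeningResult:
    table: pd.DataFrame          # predictor x outcome: p, selected, status
    selected: list               # union list entering the joint model
    threshold: float
    per_outcome: dict = field(default_factory=dict)


def screen(df: pd.DataFrame, candidates, spec: ModelSpec | None = None,
           threshold: float = 0.20, nodes: int = 31) -> ScreeningResult:
    """Run the univariate entry stage over all candidate predictors."""
    spec = spec or ModelSpec()
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be a probability")
    missing = [c for c in candidates if c not in df.columns]
    if missing:
        raise ValueError(f"candidate predictors absent from data: {missing}")

    rows = []
    per_outcome = {spec.outcome1: [], spec.outcome2: []}
    null_ll = {}
    for outcome in (spec.outcome1, spec.outcome2):
        null_fit = fit_univariate(df, None, outcome, spec, nodes=nodes,
                                  compute_cov=False)
        null_ll[outcome] = null_fit.loglik
        for pred in candidates:
            try:
                fit = fit_univariate(df, pred, outcome, spec, nodes=nodes,
                                     compute_cov=False)
                ok = fit.converged and np.isfinite(fit.loglik)
            except Exception as err:  # degenerate designs etc.
                logger.warning("screen: %s on %s failed: %s", pred, outcome, err)
                ok = False
            if not ok:
                rows.append((pred, outcome, np.nan, False, "undetermined"))
                logger.warning("screen: %s on %s undetermined (non-convergence)",
                               pred, outcome)
                continue
            lrt = max(0.0, 2.0 * (fit.loglik - null_ll[outcome]))
            p = float(stats.chi2.sf(lrt, 2))
            selected = bool(p < threshold)
            rows.append((pred, outcome, p, selected, "ok"))
            if selected:
                per_outcome[outcome].append(pred)
            logger.info("screen: %s on %s: LRT p=%.4g -> %s", pred, outcome, p,
                        "selected" if selected else "not selected")

    table = pd.DataFrame(rows, columns=["predictor", "outcome", "p",
                                        "selected", "status"])
    union = [c for c in candidates
             if c in per_outcome[spec.outcome1] or c in per_outcome[spec.outcome2]]
    return ScreeningResult(table=table, selected=union, threshold=threshold,
                           per_outcome=per_outcome)
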