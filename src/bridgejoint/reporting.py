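"""Rendering and serialisation of fitted results.

Rendered tables mirror the conventional epidemiological layout: one block
per outcome, ``OR (lower-upper)`` at two decimals, reference levels of
binary predictors labelled "Reference category".  Machine-readable outputs
(CSV/JSON) keep full precision and are byte-deterministic for a given fit.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = ["render_or_table", "results_to_dict", "write_results_json",
           "write_or_csv"]


def _num(v) -> str:
    if not np.isfinite(v):
        return "-"
    if v != 0.0 and not 0.005 <= v <= 999.0:
        return f"{v:.2g}"
    return f"{v:.2f}"


def _fmt(or_, lo, hi) -> str:
    if not np.isfinite(lo):
        return f"{_num(or_)} (se unavailable)"
    return f"{_num(or_)} ({_num(lo)}-{_num(hi)})"


def render_or_table(fit, level: float = 0.95) -> str:
    """Two-block odds-ratio table of a converged joint fit."""
    if not fit.converged:
        return ("Model did not converge; no odds-ratio table.\n"
                f"Diagnostics: {fit.diagnostics}")
    spec = fit.model.design.spec
    table = fit.or_table(level)
    binary_levels = spec.binary_levels
    width = 24
    lines = []
    for outcome, cats in [(spec.outcome1, spec.categories1),
                          (spec.outcome2, spec.categories2)]:
        block = table[table["outcome"] == outcome]
        contrasts = [f"{cats[1]} to {cats[0]}", f"{cats[2]} to {cats[0]}"]
        lines.append(f"{outcome} — OR ({level:.0%} CI)")
        header = "Predictor".ljust(width) + "".join(c.ljust(width) for c in contrasts)
        lines.append(header)
        for pred in block["predictor"].unique():
            sub = block[block["predictor"] == pred].reset_index()
            cells = [_fmt(r["OR"], r["ci_low"], r["ci_high"])
                     for _, r in sub.iterrows()]
            if pred in binary_levels:
                ref, event = binary_levels[pred]
                lines.append(pred.ljust(width))
                lines.append(("  " + event).ljust(width)
                             + "".join(c.ljust(width) for c in cells))
                lines.append(("  " + ref).ljust(width) + "Reference category")
            else:
                lines.append(pred.ljust(width) + "".join(c.ljust(width) for c in cells))
        lines.append("")
    return "\n".join(lines)


def results_to_dict(fit) -> dict:
    """JSON-ready summary of a joint fit (full precision)."""
    p = fit.params
    return {
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
        "n_clusters": fit.n_clusters,
        "omega": p.omega.tolist(),
        "alpha": p.alpha.tolist(),
        "theta": p.theta.tolist(),
        "beta": p.beta.tolist(),
        "phi1": p.phi1,
        "phi2": p.phi2,
        "rho": p.rho,
        "predictors1": list(p.names1),
        "predictors2": list(p.names2),
        "diagnostics": {k: v for k, v in fit.diagnostics.items()
                        if isinstance(v, (int, float, str, type(None)))},
    }


def write_results_json(fit, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results_to_dict(fit), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_or_csv(fit, path, level: float = 0.95) -> None:
    fit.or_table(level).to_csv(path, index=False, float_format="%.10g")
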