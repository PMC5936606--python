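"""End-to-end workflow: descriptives -> univariate screening -> joint fit ->
odds-ratio report, driven by a plain-text (YAML) config.

All machine-readable outputs (CSV/JSON) are byte-deterministic functions of
the config, including its seed; logs (with timings) go to the logger, never
into the output files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .descriptives import crosstab, group_summary, pearson_chi2, prevalence
from .design import ModelSpec, default_spec
from .model import fit_joint
from .reporting import render_or_table, write_or_csv, write_results_json
from .screening import screen
from .simulate import CohortConfig, paper_like_cohort, read_cohort, write_cohort

logger = logging.getLogger("bridgejoint")

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_CANDIDATES = [
    "mother_age", "father_age", "ses", "bmi", "parity", "mother_education",
    "father_education", "occupation", "pregnancy_type", "abortion_history",
    "stillbirth_history", "preeclampsia", "art", "multiple_pregnancy",
    "infant_sex",
]


@dataclass
class PipelineConfig:
    input: str | None = None          # cohort CSV; None -> simulate
    seed: int = 0
    n_clusters: int = 30
    total_n: int = 4415
    candidates: list = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    threshold: float = 0.20
    nodes: int = 21
    level: float = 0.95
    outdir: str = "bridgejoint_out"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold < 1.0:
            raise ValueError("screening threshold must lie in [0, 1)")
        if self.nodes < 5:
            raise ValueError("need at least 5 quadrature nodes")
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name):
    logger.info("pipeline stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a dict of output paths and key results.

    A stage failure is logged with the stage name and aborts the downstream
    stages (the exception propagates).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = default_spec()
    results: dict = {"outdir": str(out), "seed": config.seed}
    logger.info("pipeline seed: %d", config.seed)

    # -- data ---------------------------------------------------------------
    t0 = _stage("data")
    if config.input:
        cohort = read_cohort(config.input)
    else:
        cohort, _truth = paper_like_cohort(config.seed, config.n_clusters,
                                           config.total_n)
        write_cohort(cohort, out / "cohort.csv", seed=config.seed)
        results["cohort"] = str(out / "cohort.csv")
    logger.info("data: %d rows, %d clusters (%.2fs)", len(cohort),
                cohort[spec.cluster].nunique(), time.perf_counter() - t0)

    # -- descriptives ---------------------------------------------------------
    t0 = _stage("descriptives")
    prev = pd.DataFrame({
        "outcome": [spec.outcome1] * 3 + [spec.outcome2] * 3,
        "category": list(spec.categories1) + list(spec.categories2),
        "percent": np.r_[prevalence(cohort, spec.outcome1, spec.categories1)
                         .to_numpy(),
                         prevalence(cohort, spec.outcome2, spec.categories2)
                         .to_numpy()],
    })
    prev.to_csv(out / "prevalence.csv", index=False, float_format="%.10g")
    ct = crosstab(cohort, spec.outcome2, spec.outcome1,
                  row_order=spec.categories2, col_order=spec.categories1)
    ct.table.to_csv(out / "outcome_crosstab.csv")
    stat, dof, p = pearson_chi2(ct)
    with open(out / "outcome_association.json", "w", encoding="utf-8") as fh:
        json.dump({"pearson_chi2": stat, "df": dof, "p": p}, fh,
                  indent=2, sort_keys=True)
        fh.write("\n")
    for outcome, tag in [(spec.outcome1, "gestational_age"),
                         (spec.outcome2, "birth_weight")]:
        gs = group_summary(cohort, outcome,
                           [c for c in config.candidates if c in cohort.columns])
        gs.to_csv(out / f"summary_by_{tag}.csv", index=False,
                  float_format="%.10g")
    results["chi2"] = stat
    logger.info("descriptives done (%.2fs)", time.perf_counter() - t0)

    # -- screening ------------------------------------------------------------
    t0 = _stage("screening")
    scr = screen(cohort, config.candidates, spec, threshold=config.threshold,
                 nodes=config.nodes)
    scr.table.to_csv(out / "screening.csv", index=False, float_format="%.10g")
    results["selected"] = scr.selected
    logger.info("screening: %d/%d predictors selected (%.2fs)",
                len(scr.selected), len(config.candidates),
                time.perf_counter() - t0)

    # -- joint fit -------------------------------------------------------------
    t0 = _stage("joint fit")
    pred1 = [p for p in scr.per_outcome[spec.outcome1]]
    pred2 = [p for p in scr.per_outcome[spec.outcome2]]
    if not pred1 and not pred2:
        logger.warning("no predictors passed screening; fitting "
                       "intercept-only joint model")
    fit = fit_joint(cohort, spec.with_predictors(pred1, pred2),
                    nodes=config.nodes)
    write_results_json(fit, out / "fit.json")
    write_or_csv(fit, out / "or_table.csv", level=config.level)
    results["fit"] = str(out / "fit.json")
    results["converged"] = fit.converged
    logger.info("joint fit: converged=%s loglik=%.3f (%.2fs)",
                fit.converged, fit.loglik, time.perf_counter() - t0)

    # -- report ---------------------------------------------------------------
    t0 = _stage("report")
    text = render_or_table(fit, level=config.level)
    (out / "report.txt").write_text(text, encoding="utf-8")
    results["report"] = str(out / "report.txt")
    logger.info("report written (%.2fs)", time.perf_counter() - t0)
    return results
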