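"""Model specification and design-matrix construction from a flat cohort table.

The analysis consumes one row per mother: a hospital (cluster) id, covariates,
and two 3-category outcomes — gestational age (preterm / term / postterm,
reference ``term``) and birth weight (LBW / normal / macrosomia, reference
``normal``).  Binary covariates are coded 0/1 against the conventional
reference levels ("No", "Female", "Undergraduate", ...); continuous
covariates pass through unchanged.  Rows with missing values in any used
column are dropped (complete-case analysis) with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("bridgejoint")

__all__ = ["ModelSpec", "DesignData", "build_design", "default_spec",
           "DEFAULT_BINARY_LEVELS"]

#: label coding for binary covariates: column -> (reference level, event level)
DEFAULT_BINARY_LEVELS: dict[str, tuple[str, str]] = {
    "parity": ("1", "2+"),
    "mother_education": ("Undergraduate", "Graduate"),
    "father_education": ("Undergraduate", "Graduate"),
    "occupation": ("Housewife", "Employed"),
    "pregnancy_type": ("Wanted", "Unwanted"),
    "abortion_history": ("No", "Yes"),
    "stillbirth_history": ("No", "Yes"),
    "preeclampsia": ("No", "Yes"),
    "art": ("No", "Yes"),
    "multiple_pregnancy": ("No", "Yes"),
    "infant_sex": ("Female", "Male"),
}


@dataclass
class ModelSpec:
    """Names, category orders and covariate coding for one joint fit."""

    outcome1: str = "gestational_age"
    categories1: tuple = ("term", "preterm", "postterm")  # reference first
    outcome2: str = "birth_weight"
    categories2: tuple = ("normal", "LBW", "macrosomia")  # reference first
    predictors1: list = field(default_factory=list)
    predictors2: list = field(default_factory=list)
    cluster: str = "hospital"
    binary_levels: dict = field(default_factory=lambda: dict(DEFAULT_BINARY_LEVELS))

    def __post_init__(self) -> None:
        for cats in (self.categories1, self.categories2):
            if len(cats) != 3:
                raise ValueError("each outcome must have exactly three categories "
                                 f"(reference first); got {cats}")

    @property
    def ref1(self) -> str:
        return self.categories1[0]

    @property
    def ref2(self) -> str:
        return self.categories2[0]

    def with_predictors(self, predictors1, predictors2) -> "ModelSpec":
        return ModelSpec(self.outcome1, self.categories1, self.outcome2,
                         self.categories2, list(predictors1), list(predictors2),
                         self.cluster, dict(self.binary_levels))


def default_spec() -> ModelSpec:
    """The perinatal two-outcome specification with the final-model predictors."""
    return ModelSpec(
        predictors1=["mother_age", "ses", "mother_education", "preeclampsia",
                     "art", "multiple_pregnancy"],
        predictors2=["mother_age", "bmi", "mother_education",
                     "stillbirth_history", "multiple_pregnancy",
                     "preeclampsia", "infant_sex"],
    )


@dataclass
class DesignData:
    """Complete-case design matrices, coded outcomes and cluster indices."""

    X1: np.ndarray           # (n, p1)
    X2: np.ndarray           # (n, p2)
    y1: np.ndarray           # int codes, 0 = reference
    y2: np.ndarray           # int codes, 0 = reference
    cluster_codes: np.ndarray
    cluster_labels: np.ndarray
    names1: list
    names2: list
    spec: ModelSpec
    n_dropped: int = 0

    @property
    def n_obs(self) -> int:
        return self.y1.size

    @property
    def n_clusters(self) -> int:
        return self.cluster_labels.size

    def subset(self, mask) -> "DesignData":
        mask = np.asarray(mask)
        codes, labels = _recode_clusters(self.cluster_labels[self.cluster_codes[mask]])
        return DesignData(self.X1[mask], self.X2[mask], self.y1[mask], self.y2[mask],
                          codes, labels, self.names1, self.names2, self.spec)


def _recode_clusters(values) -> tuple[np.ndarray, np.ndarray]:
    labels, codes = np.unique(np.asarray(values), return_inverse=True)
    return codes.astype(np.int64), labels


def _code_outcome(series: pd.Series, categories, column: str) -> np.ndarray:
    mapping = {lab: code for code, lab in enumerate(categories)}
    vals = series.map(mapping)
    if vals.isna().any():
        bad = series[vals.isna()]
        row = bad.index[0]
        raise ValueError(f"unknown category {bad.iloc[0]!r} in column {column!r} "
                         f"(first offending row index {row})")
    return vals.to_numpy(dtype=np.int64)


def _code_predictor(series: pd.Series, column: str, binary_levels: dict) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(series):
        return series.to_numpy(dtype=float)
    if column not in binary_levels:
        raise ValueError(f"no coding rule for non-numeric column {column!r}")
    ref, event = binary_levels[column]
    mapping = {ref: 0.0, event: 1.0}
    vals = series.map(mapping)
    if vals.isna().any():
        bad = series[vals.isna()]
        raise ValueError(f"unknown category {bad.iloc[0]!r} in column {column!r} "
                         f"(first offending row index {bad.index[0]}); "
                         f"expected {ref!r} or {event!r}")
    return vals.to_numpy(dtype=float)


def build_design(df: pd.DataFrame, spec: ModelSpec) -> DesignData:
    """Code a raw cohort table into the matrices the likelihood consumes."""
    used = ([spec.cluster, spec.outcome1, spec.outcome2]
            + list(dict.fromkeys(list(spec.predictors1) + list(spec.predictors2))))
    missing_cols = [c for c in used if c not in df.columns]
    if missing_cols:
        raise ValueError(f"input table lacks required columns: {missing_cols}")
    for col in used:
        if df[col].isna().all():
            raise ValueError(f"column {col!r} is entirely missing")

    sub = df[used]
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("build_design: dropped %d incomplete rows (complete-case)", n_dropped)
    sub = sub.loc[keep]

    y1 = _code_outcome(sub[spec.outcome1], spec.categories1, spec.outcome1)
    y2 = _code_outcome(sub[spec.outcome2], spec.categories2, spec.outcome2)
    codes, labels = _recode_clusters(sub[spec.cluster].to_numpy())

    def matrix(predictors):
        if not predictors:
            return np.empty((len(sub), 0))
        cols = [_code_predictor(sub[c], c, spec.binary_levels) for c in predictors]
        return np.column_stack(cols)

    return DesignData(matrix(spec.predictors1), matrix(spec.predictors2), y1, y2,
                      codes, labels, list(spec.predictors1), list(spec.predictors2),
                      spec, n_dropped)
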