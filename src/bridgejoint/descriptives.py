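"""Descriptive statistics: prevalences, outcome cross-tabulation with the
Pearson chi-square test of association, and per-group covariate summaries
(mean +/- SD with one-way ANOVA for continuous variables; counts (%) with a
chi-square test for categorical ones)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ContingencyTable", "crosstab", "pearson_chi2", "prevalence",
           "group_summary", "load_reported_outcome_crosstab",
           "REPORTED_GROUP_SIZES"]

#: printed group sizes of the two outcomes in the source cohort (n = 4415)
REPORTED_GROUP_SIZES = {
    "gestational_age": {"preterm": 244, "term": 4149, "postterm": 22},
    "birth_weight": {"LBW": 213, "normal": 4078, "macrosomia": 124},
}


@dataclass
class ContingencyTable:
    """Observed cross-tabulation with margins."""

    table: pd.DataFrame  # rows x columns of nonnegative integer counts

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def counts(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.counts.sum())


def crosstab(df: pd.DataFrame, var_row: str, var_col: str,
             row_order=None, col_order=None) -> ContingencyTable:
    """Observed counts of ``var_row`` by ``var_col``."""
    for col in (var_row, var_col):
        if (len(df) and col in df.columns
                and pd.api.types.is_float_dtype(df[col])):
            raise ValueError(f"{col!r} is continuous, not categorical")
    table = pd.crosstab(df[var_row], df[var_col]) if len(df) else pd.DataFrame()
    if row_order is not None:
        table = table.reindex(index=row_order, fill_value=0)
    if col_order is not None:
        table = table.reindex(columns=col_order, fill_value=0)
    return ContingencyTable(table)


def pearson_chi2(table: ContingencyTable):
    """Plain Pearson chi-square (no continuity correction).

    Zero row/column margins are dropped with a warning and the degrees of
    freedom adjusted accordingly.
    """
    counts = table.counts
    if counts.sum() <= 0:
        raise ValueError("contingency table has no observations")
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns from chi-square test",
                      stacklevel=2)
        counts = counts[keep_r][:, keep_c]
    r, c = counts.shape
    if r < 2 or c < 2:
        raise ValueError("chi-square needs at least a 2x2 table after "
                         "dropping empty margins")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def prevalence(data, outcome: str | None = None, categories=None) -> pd.Series:
    """Category percentages (full precision; the reporting layer rounds).

    ``data`` may be a cohort DataFrame (then ``outcome`` names the column) or
    a mapping/Series of category counts.
    """
    if isinstance(data, pd.DataFrame):
        if len(data) == 0:
            raise ValueError("empty dataset")
        counts = data[outcome].value_counts()
    else:
        counts = pd.Series(data, dtype=float)
    if categories is not None:
        counts = counts.reindex(categories, fill_value=0)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no observations to compute prevalences from")
    return 100.0 * counts / total


def group_summary(df: pd.DataFrame, groupvar: str, variables=None) -> pd.DataFrame:
    """Per-outcome-group covariate summary table.

    Continuous variables get ``mean +/- sd`` per group and a one-way ANOVA
    p-value; categoricals get ``count (%)`` per level and a Pearson
    chi-square p-value.  Empty groups yield blank columns with a warning.
    """
    groups = [g for g in df[groupvar].dropna().unique()]
    if variables is None:
        variables = [c for c in df.columns if c != groupvar]
    rows = []
    for var in variables:
        sub = df[[var, groupvar]].dropna()
        by_group = {g: sub.loc[sub[groupvar] == g, var] for g in groups}
        empties = [g for g, v in by_group.items() if len(v) == 0]
        if empties:
            warnings.warn(f"group(s) {empties} empty for variable {var!r}",
                          stacklevel=2)
        continuous = (pd.api.types.is_numeric_dtype(sub[var])
                      and (pd.api.types.is_float_dtype(sub[var])
                           or sub[var].nunique() > 2))
        if continuous:
            samples = [v.to_numpy(dtype=float) for v in by_group.values() if len(v)]
            if len(samples) >= 2 and any(np.ptp(s) > 0 for s in samples):
                stat, p = stats.f_oneway(*samples)
            else:
                stat, p = 0.0, 1.0
            cells = {g: (f"{v.mean():.2f} ± {v.std(ddof=1):.2f}" if len(v) else "")
                     for g, v in by_group.items()}
            rows.append({"variable": var, "level": "", **cells,
                         "test": "anova", "p": float(p)})
        else:
            ct = pd.crosstab(sub[var], sub[groupvar]).reindex(columns=groups,
                                                              fill_value=0)
            try:
                chi_p = pearson_chi2(ContingencyTable(ct))[2]
            except ValueError:
                chi_p = np.nan
            row_tot = ct.sum(axis=1)
            for level in ct.index:
                cells = {}
                for g in groups:
                    n = int(ct.loc[level, g])
                    pct = 100.0 * n / row_tot[level] if row_tot[level] else 0.0
                    cells[g] = f"{n} ({pct:.1f})"
                rows.append({"variable": var, "level": str(level), **cells,
                             "test": "chi2", "p": float(chi_p)})
                chi_p = np.nan  # print the test once per variable
    return pd.DataFrame(rows)


def load_reported_outcome_crosstab() -> ContingencyTable:
    """The published birth-weight by gestational-age cross-tab (n = 4415)."""
    with resources.files("bridgejoint.data").joinpath(
            "outcome_crosstab.csv").open() as fh:
        table = pd.read_csv(fh, index_col=0)
    return ContingencyTable(table)
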