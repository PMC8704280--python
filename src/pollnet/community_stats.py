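"""Per-sampling-event summaries and group-comparison statistics.

Each (zone, site, period) sampling event yields richness and abundance
summaries; zones are compared with generalized linear models (Gaussian,
Poisson or quasi-Poisson family) followed by pairwise contrasts of the
model's group means on the link scale with Tukey-style multiplicity
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = ["summarize_events", "GroupComparison", "compare_groups", "RESPONSES"]

RESPONSES = (
    "pollinator_richness",
    "plant_richness",
    "pollinator_abundance",
    "flower_abundance",
)

Family = Literal["gaussian", "poisson", "quasipoisson"]


def summarize_events(
    records: pd.DataFrame,
    flower_counts: pd.DataFrame | None = None,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per (zone, site, period) sampling event.

    Columns: pollinator_richness, plant_richness, pollinator_abundance and,
    when a flower-count table (zone, site, period, plant, flowers) is given,
    flower_abundance.  ``design`` optionally lists every visited
    (zone, site, period); declared events with no captures appear zero-filled,
    and flower counts referencing an undeclared site raise.
    """
    if len(records) == 0:
        raise ValueError("no records")
    keys = ["zone", "site", "period"]
    summary = (
        records.groupby(keys)
        .agg(
            pollinator_richness=("pollinator", "nunique"),
            plant_richness=("plant", "nunique"),
            pollinator_abundance=("count", "sum"),
        )
        .reset_index()
    )
    if design is not None:
        missing = [c for c in keys if c not in design.columns]
        if missing:
            raise ValueError(f"design table missing column(s): {missing}")
        declared = design[keys].drop_duplicates()
        summary = declared.merge(summary, on=keys, how="left").fillna(0)
        for c in ("pollinator_richness", "plant_richness", "pollinator_abundance"):
            summary[c] = summary[c].astype(int)
    if flower_counts is not None:
        required = keys + ["flowers"]
        missing = [c for c in required if c not in flower_counts.columns]
        if missing:
            raise ValueError(f"flower table missing column(s): {missing}")
        if design is not None:
            declared_sites = set(map(tuple, design[["zone", "site"]].drop_duplicates().to_numpy()))
            seen = set(map(tuple, flower_counts[["zone", "site"]].drop_duplicates().to_numpy()))
            undeclared = seen - declared_sites
            if undeclared:
                raise ValueError(f"flower counts reference undeclared site(s): {sorted(undeclared)}")
        fl = flower_counts.groupby(keys)["flowers"].sum().rename("flower_abundance").reset_index()
        summary = summary.merge(fl, on=keys, how="left")
        summary["flower_abundance"] = summary["flower_abundance"].fillna(0).astype(int)
    return summary


@dataclass(frozen=True)
class GroupComparison:
    """Overall GLM group test plus pairwise link-scale contrasts."""

    response: str
    family: str
    df_between: int
    statistic: float
    statistic_name: str  # "F" or "deviance_chi2"
    p_value: float
    contrasts: pd.DataFrame  # columns: group_a, group_b, estimate, se, stat, p_adj
    group_means: pd.DataFrame  # link-scale mean and response-scale mean per group
    degenerate: bool = False


def _glm_family(family: Family) -> sm.families.Family:
    if family == "gaussian":
        return sm.families.Gaussian()
    if family in ("poisson", "quasipoisson"):
        return sm.families.Poisson()
    raise ValueError(f"unknown family: {family!r}")


def compare_groups(
    summaries: pd.DataFrame,
    response: str,
    family: Family,
    group_col: str = "zone",
) -> GroupComparison:
    """Fit ``response ~ group`` with the requested GLM family and compare groups.

    The overall test is an F test (deviance drop over estimated dispersion)
    for Gaussian and quasi-Poisson fits and a deviance chi-square for
    Poisson.  Pairwise contrasts are differences of group means on the link
    scale (identity for Gaussian, log otherwise) with Tukey studentized-range
    adjustment.
    """
    if response not in summaries.columns:
        raise ValueError(f"unknown response column: {response!r}")
    data = summaries[[group_col, response]].dropna()
    groups = sorted(data[group_col].unique())
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = data.groupby(group_col).size()
    if (counts < 2).any():
        raise ValueError("need at least 2 observations per group")
    y = data[response].to_numpy(dtype=float)
    X = pd.get_dummies(data[group_col], dtype=float)[groups].to_numpy()  # cell-means coding
    n = len(y)

    if float(np.var(y)) == 0.0:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
        contrasts = pd.DataFrame(
            {"group_a": [p[0] for p in pairs], "group_b": [p[1] for p in pairs],
             "estimate": 0.0, "se": np.nan, "stat": 0.0, "p_adj": 1.0}
        )
        means = pd.DataFrame({"link_mean": np.nan, "mean": y[0]}, index=pd.Index(groups, name=group_col))
        return GroupComparison(response, family, k - 1, 0.0, "F", 1.0, contrasts, means, degenerate=True)

    fam = _glm_family(family)
    fit = sm.GLM(y, X, family=fam).fit()
    null_fit = sm.GLM(y, np.ones((n, 1)), family=fam).fit()
    df_between = k - 1
    df_resid = n - k

    if family == "gaussian":
        dispersion = fit.deviance / df_resid
    elif family == "quasipoisson":
        dispersion = float(fit.pearson_chi2) / df_resid
    else:
        dispersion = 1.0

    if family in ("gaussian", "quasipoisson"):
        stat = (null_fit.deviance - fit.deviance) / df_between / dispersion
        p = float(scipy.stats.f.sf(stat, df_between, df_resid))
        stat_name = "F"
        t_df = df_resid
    else:
        stat = null_fit.deviance - fit.deviance
        p = float(scipy.stats.chi2.sf(stat, df_between))
        stat_name = "deviance_chi2"
        t_df = np.inf

    # pairwise contrasts on the link scale (cell-means coding: params are group means)
    cov = np.asarray(fit.cov_params()) * (dispersion if family == "quasipoisson" else 1.0)
    beta = np.asarray(fit.params)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            est = beta[i] - beta[j]
            se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
            z = est / se if se > 0 else 0.0
            df_tukey = t_df if np.isfinite(t_df) else 1e7
            p_adj = float(scipy.stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, df_tukey))
            rows.append((groups[i], groups[j], float(est), se, float(z), min(p_adj, 1.0)))
    contrasts = pd.DataFrame(rows, columns=["group_a", "group_b", "estimate", "se", "stat", "p_adj"])
    means = pd.DataFrame(
        {"link_mean": beta, "mean": fam.link.inverse(beta)},
        index=pd.Index(groups, name=group_col),
    )
    return GroupComparison(response, family, df_between, float(stat), stat_name, p, contrasts, means)
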