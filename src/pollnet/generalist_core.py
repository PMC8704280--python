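"""Core-generalist scores, core/periphery coverage, singleton shares, nested ranks.

The generalization score of a pollinator is the z-score of its mean per-site
distinct-partner count relative to the zone's pollinator community; scores
above 1 mark the generalist core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .data_model_io import InteractionMatrix, ZoneCollection

__all__ = [
    "gc_scores",
    "core_generalists",
    "CoreSummary",
    "singleton_share",
    "nested_rank",
]

GC_COLUMNS = [
    "group", "k", "gc", "n_individuals", "pct_individuals",
    "unique_partners", "pct_unique_interactions", "is_core",
]


@dataclass(frozen=True)
class CoreSummary:
    """Coverage of the generalist core: share of individuals and of unique links."""

    core_species: tuple[str, ...]
    pct_individuals: float
    pct_unique_interactions: float


def gc_scores(
    zone: ZoneCollection,
    include_absent_sites: bool = True,
    sd_mode: Literal["sample", "population"] = "sample",
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-pollinator generalization table for one zone.

    ``k`` is the mean over the zone's sites of the per-site count of distinct
    plant partners; sites where the species is absent contribute 0 when
    ``include_absent_sites`` (default), otherwise they are skipped.  ``gc`` is
    the z-score of ``k`` over the zone's pollinators, with the sample (n-1)
    standard deviation by default.

    Returns a DataFrame indexed by pollinator label with columns: group, k,
    gc, n_individuals, pct_individuals, unique_partners,
    pct_unique_interactions, is_core.
    """
    pooled = zone.pooled
    species = list(pooled.pollinator_labels)
    if len(species) < 2:
        raise ValueError("need at least 2 pollinator species")

    per_site = pd.DataFrame(0, index=species, columns=[s.site for s in zone.sites])
    for sn in zone.sites:
        deg = (sn.matrix.counts > 0).sum(axis=0)
        per_site.loc[list(sn.matrix.pollinator_labels), sn.site] = deg
    if include_absent_sites:
        k = per_site.mean(axis=1)
    else:
        k = per_site.where(per_site > 0).mean(axis=1)

    ddof = 1 if sd_mode == "sample" else 0
    sd = float(k.std(ddof=ddof))
    if sd < 1e-12:
        raise ValueError("degenerate input: all pollinator species have identical k")
    gc = (k - k.mean()) / sd

    n_ind = pooled.counts.sum(axis=0)
    partners = (pooled.counts > 0).sum(axis=0)
    table = pd.DataFrame(
        {
            "group": [
                (zone.species_groups or {}).get(sp, pd.NA) for sp in species
            ],
            "k": k.to_numpy(),
            "gc": gc.to_numpy(),
            "n_individuals": n_ind,
            "pct_individuals": 100.0 * n_ind / pooled.m,
            "unique_partners": partners,
            "pct_unique_interactions": 100.0 * partners / pooled.n_links,
            "is_core": gc.to_numpy() > threshold,
        },
        index=pd.Index(species, name="pollinator"),
    )
    return table.sort_values("gc", ascending=False)


def core_generalists(gc_table: pd.DataFrame, threshold: float = 1.0) -> CoreSummary:
    """Species with gc above the threshold and the coverage they provide."""
    core = gc_table[gc_table["gc"] > threshold]
    return CoreSummary(
        core_species=tuple(core.index),
        pct_individuals=float(core["pct_individuals"].sum()),
        pct_unique_interactions=float(core["pct_unique_interactions"].sum()),
    )


def singleton_share(
    zone: ZoneCollection,
    definition: Literal["one_individual", "one_link"] = "one_individual",
) -> float:
    """Percent of zone-level unique interactions held by singleton pollinators.

    A singleton is a species with exactly one recorded individual
    (``one_individual``, default) or exactly one unique plant partner
    (``one_link``).
    """
    pooled = zone.pooled
    if pooled.m == 0:
        raise ValueError("empty zone")
    n_ind = pooled.counts.sum(axis=0)
    partners = (pooled.counts > 0).sum(axis=0)
    if definition == "one_individual":
        singleton = n_ind == 1
    elif definition == "one_link":
        singleton = partners == 1
    else:
        raise ValueError(f"unknown singleton definition: {definition!r}")
    return float(100.0 * partners[singleton].sum() / pooled.n_links)


def nested_rank(M: InteractionMatrix) -> pd.DataFrame:
    """Rank pollinators from most (rank 1) to least generalized.

    Ordering: decreasing number of distinct plant partners, ties broken by
    decreasing total interaction count, then lexicographic label.
    """
    if M.m == 0:
        raise ValueError("empty interaction matrix")
    degree = (M.counts > 0).sum(axis=0)
    abundance = M.counts.sum(axis=0)
    table = pd.DataFrame(
        {"degree": degree, "abundance": abundance},
        index=pd.Index(M.pollinator_labels, name="pollinator"),
    )
    table = table.sort_values(
        by=["degree", "abundance", "pollinator"],
        ascending=[False, False, True],
        kind="stable",
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table[["rank", "degree", "abundance"]]
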