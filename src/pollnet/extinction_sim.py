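"""Targeted removal of pollinator species and the resulting nestedness change.

Named species are deleted from every site network of a zone; per-site NODF is
recomputed on the trimmed matrices and averaged across all sites, and the
percent change relative to the intact zone mean is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .data_model_io import InteractionMatrix, ZoneCollection
from .generalist_core import nested_rank
from .network_metrics import nodf

__all__ = ["RemovalResult", "remove_pollinators", "simulate_removal", "rank_removal_sweep"]


@dataclass(frozen=True)
class RemovalResult:
    """Before/after nestedness bookkeeping for one targeted-extinction experiment."""

    removed: frozenset[str]
    site_nodf_before: dict[str, float]
    site_nodf_after: dict[str, float]
    mean_nodf_before: float
    mean_nodf_after: float
    percent_change: float
    excluded_sites: tuple[str, ...] = ()


def remove_pollinators(M: InteractionMatrix, species: Iterable[str]) -> InteractionMatrix:
    """Delete named pollinator columns; trim plant rows left with zero marginal.

    Species absent from the matrix are ignored; removing every column raises.
    """
    species = set(species)
    if not species:
        raise ValueError("species set is empty")
    return M.drop_pollinators(species)


def simulate_removal(
    zone: ZoneCollection,
    species: Iterable[str],
    occupied_only: bool = False,
) -> RemovalResult:
    """Remove named species from every site of a zone and re-average NODF.

    Sites where none of the named species occur keep their original NODF in
    the after-mean (set ``occupied_only`` to average only over sites where a
    removal actually happened).  Sites whose post-removal matrix is too small
    for NODF are excluded from the after-mean with a warning.
    """
    species = frozenset(species)
    present = {
        sp for sp in species for sn in zone.sites if sp in sn.matrix.pollinator_labels
    }
    missing = species - present
    if species and missing:
        raise ValueError(
            f"species absent from every site of zone {zone.zone}: {sorted(missing)}"
        )

    before: dict[str, float] = {}
    after: dict[str, float] = {}
    excluded: list[str] = []
    for sn in zone.sites:
        before[sn.site] = nodf(sn.matrix)
        touched = species & set(sn.matrix.pollinator_labels)
        if not touched:
            after[sn.site] = before[sn.site]
            continue
        try:
            reduced = sn.matrix.drop_pollinators(touched)
            after[sn.site] = nodf(reduced)
        except ValueError as exc:
            warnings.warn(
                f"site {sn.site}: NODF undefined after removal ({exc}); site excluded",
                stacklevel=2,
            )
            excluded.append(sn.site)

    if occupied_only:
        touched_sites = [
            sn.site for sn in zone.sites
            if species & set(sn.matrix.pollinator_labels) and sn.site not in excluded
        ]
        after_vals = [after[s] for s in touched_sites]
        before_vals = [before[s] for s in touched_sites]
    else:
        after_vals = [v for s, v in after.items()]
        before_vals = [before[s] for s in after]
    if not after_vals:
        raise ValueError("no site retains a defined NODF after removal")
    mean_before = sum(before_vals) / len(before_vals)
    mean_after = sum(after_vals) / len(after_vals)
    pct = 0.0 if not species else 100.0 * (mean_after - mean_before) / mean_before
    return RemovalResult(
        removed=species,
        site_nodf_before=before,
        site_nodf_after=after,
        mean_nodf_before=mean_before,
        mean_nodf_after=mean_after,
        percent_change=pct,
        excluded_sites=tuple(excluded),
    )


def rank_removal_sweep(zone: ZoneCollection, ranks: Sequence[int]) -> list[RemovalResult]:
    """One single-species removal per nested rank, plus the combined-set removal.

    Ranks index the intact pooled network's nested-rank table (1 = most
    generalized); ranks are not recomputed between removals.
    """
    table = nested_rank(zone.pooled)
    by_rank = {int(r): sp for sp, r in table["rank"].items()}
    bad = [r for r in ranks if int(r) not in by_rank]
    if bad:
        raise ValueError(f"invalid nested ranks for zone {zone.zone}: {bad}")
    targets = [by_rank[int(r)] for r in ranks]
    results = [simulate_removal(zone, {sp}) for sp in targets]
    results.append(simulate_removal(zone, set(targets)))
    return results
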