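"""Record and matrix data model, aggregation to site/zone networks, and file I/O.

The raw input is a long-format table of specimen records (one row per
captured insect, or per group of ``count`` identical specimens).  Records
aggregate into labelled plant x pollinator interaction-count matrices, one
per site, which pool into a zone-level collection.  All downstream indices
consume :class:`InteractionMatrix`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "InteractionMatrix",
    "SiteNetwork",
    "ZoneCollection",
    "read_records",
    "write_records",
    "build_site_networks",
    "pool_zone",
    "zones_from_records",
    "read_matrix",
    "write_matrix",
    "RECORD_COLUMNS",
    "OPTIONAL_RECORD_COLUMNS",
    "POLLINATOR_GROUPS",
]

RECORD_COLUMNS = ("zone", "site", "period", "pollinator", "plant")
OPTIONAL_RECORD_COLUMNS = ("group", "count")
POLLINATOR_GROUPS = ("bee", "fly", "lepidoptera")


class SchemaError(ValueError):
    """Raised when an input file does not declare the expected columns."""


@dataclass(frozen=True)
class InteractionMatrix:
    """Labelled non-negative integer count matrix, plants (rows) x pollinators (columns).

    Parameters
    ----------
    plant_labels : sequence of str
        Unique row labels.
    pollinator_labels : sequence of str
        Unique column labels.
    counts : array-like of int, shape (n_plants, n_pollinators)
        Interaction counts ``a_ij`` = number of specimens of pollinator ``j``
        captured on plant ``i``.
    """

    plant_labels: tuple[str, ...]
    pollinator_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        plants = tuple(str(x) for x in self.plant_labels)
        pols = tuple(str(x) for x in self.pollinator_labels)
        counts = np.asarray(self.counts)
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("interaction counts must be integers")
            counts = rounded.astype(np.int64)
        counts = counts.astype(np.int64, copy=True).reshape(len(plants), len(pols))
        if (counts < 0).any():
            raise ValueError("interaction counts must be non-negative")
        if len(set(plants)) != len(plants):
            raise ValueError("duplicate plant label")
        if len(set(pols)) != len(pols):
            raise ValueError("duplicate pollinator label")
        counts.setflags(write=False)
        object.__setattr__(self, "plant_labels", plants)
        object.__setattr__(self, "pollinator_labels", pols)
        object.__setattr__(self, "counts", counts)

    # -- basic shape / totals -------------------------------------------------
    @property
    def n_plants(self) -> int:
        return len(self.plant_labels)

    @property
    def n_pollinators(self) -> int:
        return len(self.pollinator_labels)

    @property
    def m(self) -> int:
        """Total interaction count (sum of all cells)."""
        return int(self.counts.sum())

    @property
    def n_links(self) -> int:
        """Number of unique plant-pollinator pairs observed (nonzero cells)."""
        return int((self.counts > 0).sum())

    def binary(self) -> np.ndarray:
        """Presence/absence view of the counts."""
        return self.counts > 0

    # -- derived objects ------------------------------------------------------
    def trim(self) -> "InteractionMatrix":
        """Drop rows and columns whose marginal total is zero."""
        rows = self.counts.sum(axis=1) > 0
        cols = self.counts.sum(axis=0) > 0
        if rows.all() and cols.all():
            return self
        return InteractionMatrix(
            tuple(l for l, k in zip(self.plant_labels, rows) if k),
            tuple(l for l, k in zip(self.pollinator_labels, cols) if k),
            self.counts[np.ix_(rows, cols)],
        )

    def drop_pollinators(self, species: Iterable[str]) -> "InteractionMatrix":
        """Delete named columns (ignoring absent names) and trim orphaned rows."""
        drop = set(species)
        keep = [j for j, l in enumerate(self.pollinator_labels) if l not in drop]
        if len(keep) == len(self.pollinator_labels):
            return self
        if not keep:
            raise ValueError("empty network: all pollinator columns removed")
        sub = InteractionMatrix(
            self.plant_labels,
            tuple(self.pollinator_labels[j] for j in keep),
            self.counts[:, keep],
        )
        return sub.trim()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.plant_labels, name="plant"),
            columns=list(self.pollinator_labels),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "InteractionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy())

    def __eq__(self, other: object) -> bool:  # counts is an ndarray, so spell it out
        if not isinstance(other, InteractionMatrix):
            return NotImplemented
        return (
            self.plant_labels == other.plant_labels
            and self.pollinator_labels == other.pollinator_labels
            and np.array_equal(self.counts, other.counts)
        )

    def __hash__(self) -> int:
        return hash((self.plant_labels, self.pollinator_labels, self.counts.tobytes()))


@dataclass(frozen=True)
class SiteNetwork:
    """One site's interaction matrix, tagged with its zone and site identifiers."""

    zone: str
    site: str
    matrix: InteractionMatrix


@dataclass(frozen=True)
class ZoneCollection:
    """A life zone's site-level networks plus the zone-pooled matrix.

    ``species_groups`` optionally maps pollinator labels to their order-group
    (bee / fly / lepidoptera) when the collection was built from records that
    carried one.
    """

    zone: str
    sites: tuple[SiteNetwork, ...]
    pooled: InteractionMatrix
    species_groups: Mapping[str, str] | None = None


# ---------------------------------------------------------------------------
# record table I/O
# ---------------------------------------------------------------------------

def _csv_row(index: int) -> int:
    # pandas index -> 1-based file line (header is line 1)
    return int(index) + 2


def read_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format specimen record CSV.

    Required columns: zone, site, period, pollinator, plant.  Optional:
    group (bee/fly/lepidoptera), count (positive integer, default 1).
    Malformed rows are rejected with their file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path.name}: no records")

    out = pd.DataFrame(index=df.index)
    for col in RECORD_COLUMNS:
        vals = df[col].str.strip()
        bad = vals[vals == ""].index.tolist()
        if bad:
            rows = ", ".join(str(_csv_row(i)) for i in bad[:10])
            raise ValueError(f"{path.name}: empty '{col}' at row(s) {rows}")
        out[col] = vals

    if "group" in df.columns:
        grp = df["group"].str.strip().str.lower()
        known = grp.isin(POLLINATOR_GROUPS) | (grp == "")
        if not known.all():
            bad = grp.index[~known].tolist()
            rows = ", ".join(str(_csv_row(i)) for i in bad[:10])
            raise ValueError(
                f"{path.name}: unknown group (expected one of {POLLINATOR_GROUPS}) "
                f"at row(s) {rows}"
            )
        out["group"] = grp.where(grp != "", other=pd.NA)
    else:
        out["group"] = pd.NA

    if "count" in df.columns:
        raw = df["count"].str.strip()
        counts = pd.to_numeric(raw.where(raw != "", other="1"), errors="coerce")
        bad = counts.index[counts.isna() | (counts != counts.round()) | (counts < 1)]
        if len(bad):
            rows = ", ".join(str(_csv_row(i)) for i in bad[:10])
            raise ValueError(f"{path.name}: count must be a positive integer at row(s) {rows}")
        out["count"] = counts.astype(int)
    else:
        out["count"] = 1
    return out


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    cols = list(RECORD_COLUMNS) + [c for c in OPTIONAL_RECORD_COLUMNS if c in records.columns]
    records.to_csv(path, columns=cols, index=False)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def build_site_networks(records: pd.DataFrame) -> list[SiteNetwork]:
    """Aggregate records into one :class:`SiteNetwork` per distinct (zone, site).

    Cell (i, j) is the total specimen count of pollinator j on plant i at that
    site summed across all sampling periods.  Rows/columns with zero marginal
    cannot arise here (every record contributes at least one specimen).
    """
    if len(records) == 0:
        raise ValueError("no records")
    nets: list[SiteNetwork] = []
    for (zone, site), sub in records.groupby(["zone", "site"], sort=True):
        table = (
            sub.pivot_table(
                index="plant", columns="pollinator", values="count",
                aggfunc="sum", fill_value=0,
            )
            .sort_index(axis=0)
            .sort_index(axis=1)
        )
        nets.append(SiteNetwork(str(zone), str(site), InteractionMatrix.from_dataframe(table).trim()))
    return nets


def pool_zone(
    sites: Sequence[SiteNetwork],
    species_groups: Mapping[str, str] | None = None,
) -> ZoneCollection:
    """Pool site networks of one zone: summed counts over the union of labels."""
    if not sites:
        raise ValueError("no site networks to pool")
    zones = {s.zone for s in sites}
    if len(zones) != 1:
        raise ValueError(f"cannot pool mixed zones: {sorted(zones)}")
    plants = sorted({p for s in sites for p in s.matrix.plant_labels})
    pols = sorted({p for s in sites for p in s.matrix.pollinator_labels})
    p_ix = {l: i for i, l in enumerate(plants)}
    q_ix = {l: j for j, l in enumerate(pols)}
    counts = np.zeros((len(plants), len(pols)), dtype=np.int64)
    for s in sites:
        rows = [p_ix[l] for l in s.matrix.plant_labels]
        cols = [q_ix[l] for l in s.matrix.pollinator_labels]
        counts[np.ix_(rows, cols)] += s.matrix.counts
    pooled = InteractionMatrix(tuple(plants), tuple(pols), counts)
    return ZoneCollection(zones.pop(), tuple(sites), pooled, species_groups)


def zones_from_records(records: pd.DataFrame) -> dict[str, ZoneCollection]:
    """Build every zone's collection (site networks + pooled matrix) from records."""
    groups: dict[str, str] = {}
    if records["group"].notna().any():
        mode = records.dropna(subset=["group"]).groupby("pollinator")["group"].agg(
            lambda s: s.mode().iloc[0]
        )
        groups = mode.to_dict()
    nets = build_site_networks(records)
    out: dict[str, ZoneCollection] = {}
    for zone in sorted({n.zone for n in nets}):
        zone_sites = [n for n in nets if n.zone == zone]
        out[zone] = pool_zone(zone_sites, species_groups=groups or None)
    return out


# ---------------------------------------------------------------------------
# matrix CSV I/O
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> InteractionMatrix:
    """Read a labelled matrix CSV (first column = plant labels, header = pollinators)."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.size == 0:
        raise ValueError(f"{path.name}: no interactions")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path.name}: duplicate plant label '{dup}'")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path.name}: duplicate pollinator label '{dup}'")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError(f"{path.name}: non-numeric cell")
    if np.isnan(vals.astype(float)).any():
        raise ValueError(f"{path.name}: missing cell")
    if (vals < 0).any():
        raise ValueError(f"{path.name}: negative cell")
    if not np.allclose(vals, np.rint(vals)):
        raise ValueError(f"{path.name}: non-integer cell")
    mat = InteractionMatrix.from_dataframe(df)
    if mat.m == 0:
        raise ValueError(f"{path.name}: no interactions")
    return mat


def write_matrix(matrix: InteractionMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path)
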