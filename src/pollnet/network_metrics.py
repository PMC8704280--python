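"""Network-level indices for a single interaction matrix, plus zone averaging.

Five indices: weighted connectance (entropy-based linkage density over total
species), NODF nestedness, bipartite weighted modularity Q, two-dimensional
Shannon specialization H2', and pollinator robustness to plant loss.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model_io import InteractionMatrix, ZoneCollection

__all__ = [
    "NetworkMetrics",
    "ModulePartition",
    "weighted_connectance",
    "nodf",
    "h2_prime",
    "modularity",
    "barber_q",
    "robustness_pollinators",
    "compute_metrics",
    "zone_metrics",
]

METRIC_FIELDS = ("connectance_w", "nodf", "modularity_q", "h2_prime", "robustness_r")


@dataclass(frozen=True)
class NetworkMetrics:
    """Bundle of the five indices plus basic size descriptors."""

    connectance_w: float
    nodf: float
    modularity_q: float
    h2_prime: float
    robustness_r: float
    n_plants: int
    n_pollinators: int
    n_links: int
    m: int

    def as_dict(self) -> dict[str, float | int]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ModulePartition:
    """Module assignment for every species plus the modularity it attains."""

    row_modules: Mapping[str, int]
    col_modules: Mapping[str, int]
    q: float

    @property
    def n_modules(self) -> int:
        return len(set(self.row_modules.values()) | set(self.col_modules.values()))


def _check_nonempty(M: InteractionMatrix) -> None:
    if M.n_plants == 0 or M.n_pollinators == 0 or M.m == 0:
        raise ValueError("empty interaction matrix")


# ---------------------------------------------------------------------------
# weighted connectance
# ---------------------------------------------------------------------------

def _effective_partners(counts: np.ndarray, axis: int) -> np.ndarray:
    """2**H for each vector along the axis (H = base-2 Shannon entropy)."""
    totals = counts.sum(axis=axis, keepdims=True).astype(float)
    p = np.divide(counts, totals, out=np.zeros_like(counts, dtype=float), where=totals > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 ** (-plogp.sum(axis=axis))


def weighted_connectance(M: InteractionMatrix) -> float:
    """Weighted linkage density divided by total species count; in (0, 0.5].

    LDw = 0.5 * [sum_j (a_.j / m) 2**H_j + sum_i (a_i. / m) 2**H_i] where H is
    the base-2 entropy of a species' interaction distribution.
    """
    _check_nonempty(M)
    counts = M.counts.astype(float)
    m = counts.sum()
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    ld_rows = (row_tot / m) @ _effective_partners(counts, axis=1)
    ld_cols = (col_tot / m) @ _effective_partners(counts, axis=0)
    ldw = 0.5 * (ld_rows + ld_cols)
    return float(ldw / (M.n_plants + M.n_pollinators))


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

def _nodf_axis_binary(B: np.ndarray) -> float:
    """Sum of paired nestedness over ordered row pairs of a boolean matrix."""
    fills = B.sum(axis=1)
    overlap = (B.astype(np.int64) @ B.T.astype(np.int64)).astype(float)
    total = 0.0
    n = B.shape[0]
    for i in range(n):
        for k in range(i + 1, n):
            hi, lo = (i, k) if fills[i] > fills[k] else (k, i)
            if fills[hi] > fills[lo] and fills[lo] > 0:
                total += 100.0 * overlap[hi, lo] / fills[lo]
    return total


def _nodf_axis_weighted(counts: np.ndarray) -> float:
    """Weighted variant: poorer-row cells must be positive and strictly smaller."""
    totals = counts.sum(axis=1)
    fills = (counts > 0).sum(axis=1)
    total = 0.0
    n = counts.shape[0]
    for i in range(n):
        for k in range(i + 1, n):
            hi, lo = (i, k) if totals[i] > totals[k] else (k, i)
            if totals[hi] > totals[lo] and fills[lo] > 0:
                shared = np.sum((counts[lo] > 0) & (counts[lo] < counts[hi]))
                total += 100.0 * shared / fills[lo]
    return total


def nodf(M: InteractionMatrix, weighted: bool = False) -> float:
    """Nestedness based on overlap and decreasing fill, on a 0-100 scale.

    Only ordered pairs (within rows, and within columns) whose marginal totals
    strictly decrease contribute; each contributes 100 x overlap / poorer
    degree.  The default binarizes counts to presence/absence.
    """
    _check_nonempty(M)
    P, Q = M.n_plants, M.n_pollinators
    if P < 2 and Q < 2:
        raise ValueError("NODF undefined: need at least 2 rows or 2 columns")
    if weighted:
        total = _nodf_axis_weighted(M.counts) + _nodf_axis_weighted(M.counts.T)
    else:
        B = M.binary()
        total = _nodf_axis_binary(B) + _nodf_axis_binary(B.T)
    n_pairs = P * (P - 1) / 2 + Q * (Q - 1) / 2
    return float(total / n_pairs)


# ---------------------------------------------------------------------------
# H2'
# ---------------------------------------------------------------------------

def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _h2_min_fill(row_tot: np.ndarray, col_tot: np.ndarray) -> float:
    """Entropy of the deterministic greedy minimum-entropy integer fill.

    Repeatedly place min(remaining row total, remaining column total) into the
    admissible cell with the largest such min; ties broken by lowest row index
    then lowest column index.
    """
    r = row_tot.astype(np.int64).copy()
    c = col_tot.astype(np.int64).copy()
    m = float(r.sum())
    placed: list[int] = []
    while r.sum() > 0:
        cand = np.minimum.outer(r, c)
        cand[r == 0, :] = -1
        cand[:, c == 0] = -1
        i, j = np.unravel_index(int(np.argmax(cand)), cand.shape)  # row-major: lowest i, then j
        v = int(cand[i, j])
        placed.append(v)
        r[i] -= v
        c[j] -= v
    p = np.asarray(placed, dtype=float) / m
    return _shannon(p)


def h2_prime(M: InteractionMatrix) -> float:
    """Standardized two-dimensional Shannon specialization, in [0, 1].

    0 = interactions match the outer product of the marginals (maximum
    generalization), 1 = interactions attain the marginal-constrained
    minimum-entropy configuration (maximum specialization).
    """
    _check_nonempty(M)
    if M.m < 2:
        raise ValueError("H2' undefined for m < 2")
    counts = M.counts.astype(float)
    m = counts.sum()
    p = counts.ravel() / m
    h2 = _shannon(p)
    r = counts.sum(axis=1) / m
    c = counts.sum(axis=0) / m
    h2_max = _shannon(r) + _shannon(c)  # entropy of the independent outer product
    h2_min = _h2_min_fill(M.counts.sum(axis=1), M.counts.sum(axis=0))
    if h2_max - h2_min < 1e-12:
        raise ValueError("H2' undefined: degenerate marginals (H2max == H2min)")
    return float(np.clip((h2_max - h2) / (h2_max - h2_min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# bipartite modularity
# ---------------------------------------------------------------------------

def barber_q(M: InteractionMatrix, row_labels: Sequence[int], col_labels: Sequence[int]) -> float:
    """Bipartite weighted modularity of a given module assignment.

    Integer arithmetic keeps the single-module partition at exactly 0.
    """
    counts = M.counts
    m = int(counts.sum())
    mask = np.asarray(row_labels)[:, None] == np.asarray(col_labels)[None, :]
    a_sel = int(counts[mask].sum())
    rc_sel = int(np.outer(counts.sum(axis=1), counts.sum(axis=0))[mask].sum())
    return float((a_sel - rc_sel / m) / m)


def _reassign(col: np.ndarray, own: np.ndarray, other: np.ndarray, idx: int) -> bool:
    """Move node ``idx`` of one side to its gain-maximizing module (or split off).

    ``col`` is the node's slice of B over the other side, ``own`` the labels of
    the node's side and ``other`` the labels of the opposite side (which
    determine the gain).  Returns True if the label changed.
    """
    labels, inv = np.unique(other, return_inverse=True)
    gains = np.zeros(len(labels))
    np.add.at(gains, inv, col)
    cur_mask = labels == own[idx]
    cur = float(gains[cur_mask].sum())  # 0 if the node's module has no opposite members
    best = int(np.argmax(gains))
    if gains[best] > max(cur, 0.0) + 1e-12:
        own[idx] = labels[best]
        return True
    if cur < -1e-12:  # split into a fresh singleton module (gain 0)
        own[idx] = max(int(own.max()), int(other.max())) + 1
        return True
    if own[idx] not in labels and gains[best] >= -1e-12 and labels[best] != own[idx]:
        # orphaned label with non-negative best alternative: tidy up
        own[idx] = labels[best]
        return True
    return False


def _propagate(B: np.ndarray, g_r: np.ndarray, g_c: np.ndarray, rng: np.random.Generator) -> None:
    """Alternate row/column label reassignment to the gain-maximizing module."""
    P, Q = B.shape
    for _ in range(200):
        changed = False
        for j in rng.permutation(Q):
            changed |= _reassign(B[:, j], g_c, g_r, j)
        for i in rng.permutation(P):
            changed |= _reassign(B[i, :], g_r, g_c, i)
        if not changed:
            break


def _merge(B: np.ndarray, g_r: np.ndarray, g_c: np.ndarray) -> None:
    """Greedily merge module pairs while modularity increases."""
    while True:
        labels = np.unique(np.concatenate([g_r, g_c]))
        k = len(labels)
        if k < 2:
            return
        ix = {l: a for a, l in enumerate(labels)}
        R = np.zeros((k, B.shape[0]))
        C = np.zeros((B.shape[1], k))
        for i, l in enumerate(g_r):
            R[ix[l], i] = 1
        for j, l in enumerate(g_c):
            C[j, ix[l]] = 1
        S = R @ B @ C  # S[a, b] = sum of B over rows in a, cols in b
        gain = S + S.T
        np.fill_diagonal(gain, -np.inf)
        a, b = np.unravel_index(int(np.argmax(gain)), gain.shape)
        if gain[a, b] <= 1e-12:
            return
        g_r[g_r == labels[b]] = labels[a]
        g_c[g_c == labels[b]] = labels[a]


def modularity(M: InteractionMatrix, seed: int = 0, restarts: int = 10) -> ModulePartition:
    """Maximize bipartite weighted modularity by label propagation + merging.

    Each row starts in its own module; columns join their best row module;
    labels are reassigned alternately until no gain, then module pairs are
    merged greedily while Q increases.  The best of ``restarts`` seeded
    restarts is returned; output is deterministic given (matrix, seed,
    restarts).
    """
    _check_nonempty(M)
    counts = M.counts.astype(float)
    m = counts.sum()
    B = (counts - np.outer(counts.sum(axis=1), counts.sum(axis=0)) / m) / m
    P, Q = B.shape
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for k in range(restarts):
        rng = np.random.default_rng([seed, k])
        if k == 0:
            g_r = np.arange(P)
            g_c = np.array([int(np.argmax(B[:, j])) for j in range(Q)])
        else:  # diversify: random initial module structure on both sides
            n_mod = int(rng.integers(1, P + Q + 1))
            g_r = rng.integers(0, n_mod, size=P)
            g_c = rng.integers(0, n_mod, size=Q)
        q_prev = -np.inf
        for _ in range(50):  # alternate propagation and merging to convergence
            _propagate(B, g_r, g_c, rng)
            _merge(B, g_r, g_c)
            q = float(B[g_r[:, None] == g_c[None, :]].sum())
            if q <= q_prev + 1e-12:
                break
            q_prev = q
        q = float(B[g_r[:, None] == g_c[None, :]].sum())
        if best is None or q > best[0] + 1e-12:
            best = (q, g_r.copy(), g_c.copy())
    assert best is not None
    q, g_r, g_c = best
    if q < 0.0:  # never worse than the trivial single-module partition (Q = 0)
        q, g_r, g_c = 0.0, np.zeros(P, dtype=int), np.zeros(Q, dtype=int)
    relabel = {l: a for a, l in enumerate(np.unique(np.concatenate([g_r, g_c])))}
    return ModulePartition(
        {lab: relabel[g] for lab, g in zip(M.plant_labels, g_r)},
        {lab: relabel[g] for lab, g in zip(M.pollinator_labels, g_c)},
        q,
    )


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

def _survival_area(B: np.ndarray, order: np.ndarray) -> float:
    """Area under the attack-tolerance curve for one plant removal order."""
    P, Q = B.shape
    position = np.empty(P, dtype=np.int64)
    position[order] = np.arange(P)
    # pollinator j dies right after its last remaining partner is removed
    death_step = np.array(
        [position[B[:, j]].max() + 1 if B[:, j].any() else 0 for j in range(Q)]
    )
    survivors = np.array([(death_step > t).sum() for t in range(P + 1)], dtype=float) / Q
    return float(np.trapezoid(survivors, dx=1.0 / P))


def robustness_pollinators(
    M: InteractionMatrix,
    replicates: int = 100,
    seed: int = 0,
    order: Literal["random", "degree_ascending", "degree_descending"] = "random",
) -> float:
    """Mean area under the pollinator-survival curve as plants are removed.

    Plants are removed one at a time (uniformly random order by default);
    a pollinator survives while it retains at least one link.  The curve of
    surviving pollinator fraction vs removed plant fraction is integrated by
    the trapezoid rule and averaged over replicates.
    """
    _check_nonempty(M)
    B = M.binary()
    P = M.n_plants
    degrees = B.sum(axis=1)
    if order == "degree_ascending":
        return _survival_area(B, np.argsort(degrees, kind="stable"))
    if order == "degree_descending":
        return _survival_area(B, np.argsort(-degrees, kind="stable"))
    rng = np.random.default_rng(seed)
    areas = [_survival_area(B, rng.permutation(P)) for _ in range(replicates)]
    return float(np.mean(areas))


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def compute_metrics(
    M: InteractionMatrix,
    replicates: int = 100,
    seed: int = 0,
    restarts: int = 10,
    weighted_nodf: bool = False,
) -> NetworkMetrics:
    """All five indices for one matrix."""
    return NetworkMetrics(
        connectance_w=weighted_connectance(M),
        nodf=nodf(M, weighted=weighted_nodf),
        modularity_q=modularity(M, seed=seed, restarts=restarts).q,
        h2_prime=h2_prime(M),
        robustness_r=robustness_pollinators(M, replicates=replicates, seed=seed),
        n_plants=M.n_plants,
        n_pollinators=M.n_pollinators,
        n_links=M.n_links,
        m=M.m,
    )


def zone_metrics(
    zone: ZoneCollection,
    replicates: int = 100,
    seed: int = 0,
    restarts: int = 10,
    weighted_nodf: bool = False,
) -> pd.DataFrame:
    """Per-site metrics plus their arithmetic mean (row label 'mean')."""
    if not zone.sites:
        raise ValueError("zone has no sites")
    rows = {}
    for sn in zone.sites:
        try:
            rows[sn.site] = compute_metrics(
                sn.matrix, replicates=replicates, seed=seed,
                restarts=restarts, weighted_nodf=weighted_nodf,
            ).as_dict()
        except ValueError as exc:
            raise ValueError(f"site {sn.site}: {exc}") from exc
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "site"
    df.loc["mean"] = df.mean(axis=0)
    return df
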