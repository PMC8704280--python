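"""Seeded generator of synthetic specimen-record and flower-count tables.

A Gaussian trait-matching niche model: plants carry a trait t_i, pollinators
an optimum u_j and a niche breadth b_j; the propensity of pollinator j to
visit plant i is exp(-(t_i - u_j)^2 / (2 b_j^2)).  Expected visits per
(site, period) cell scale with a sampling intensity, log-normal plant
abundances and pollinator activities, and Bernoulli site occupancy; realized
counts are Poisson and each specimen is emitted as one record row.

Heterogeneous breadths yield nested structure; clustering of traits yields
modules.  Wider mean breadth lowers network specialization, which the
three-zone elevational preset exploits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model_io import POLLINATOR_GROUPS

__all__ = ["SynthParams", "ZoneDataset", "generate_zone", "generate_flower_counts",
           "generate_dataset", "gradient_params", "preset_gradient", "design_table"]


@dataclass(frozen=True)
class SynthParams:
    """Knobs for one synthetic life zone."""

    zone: str
    n_plants: int
    n_pollinators: int
    n_sites: int = 6
    n_periods: int = 9
    plant_abund_mu: float = 0.0
    plant_abund_sigma: float = 1.0
    activity_mu: float = 0.0
    activity_sigma: float = 0.8
    niche_mu: float = -2.0       # log mean of pollinator niche breadth
    niche_sigma: float = 0.6
    intensity: float = 0.02      # sampling intensity lambda
    occupancy: float = 0.8       # per-species per-site Bernoulli occupancy
    dominance_boost: float = 1.0  # multiply the most active pollinator's activity
    group_probs: tuple[float, float, float] = (0.35, 0.45, 0.20)  # bee, fly, lepidoptera
    dominant_group: str | None = None  # force the boosted species' group
    flower_mu: float = 3.4       # log mean flowers per (site, period, plant)
    flower_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 1 or self.n_pollinators < 1 or self.n_sites < 1 or self.n_periods < 1:
            raise ValueError("species, site and period counts must be >= 1")
        if self.plant_abund_sigma < 0 or self.activity_sigma < 0 or self.niche_sigma < 0:
            raise ValueError("sigma parameters must be >= 0")
        if not self.intensity > 0:
            raise ValueError("sampling intensity must be > 0")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must be in (0, 1]")
        if abs(sum(self.group_probs) - 1.0) > 1e-9:
            raise ValueError("group_probs must sum to 1")


@dataclass(frozen=True)
class ZoneDataset:
    """Generated records + flower counts + the latent truth that produced them."""

    records: pd.DataFrame
    flowers: pd.DataFrame
    truth: dict


def _latents(params: SynthParams, rng: np.random.Generator) -> dict:
    P, Q = params.n_plants, params.n_pollinators
    traits = rng.uniform(0.0, 1.0, P)
    abund = rng.lognormal(params.plant_abund_mu, params.plant_abund_sigma, P)
    abund /= abund.mean()
    optima = rng.uniform(0.0, 1.0, Q)
    activity = rng.lognormal(params.activity_mu, params.activity_sigma, Q)
    activity /= activity.mean()
    breadth = rng.lognormal(params.niche_mu, params.niche_sigma, Q)
    groups = rng.choice(POLLINATOR_GROUPS, size=Q, p=list(params.group_probs))
    dom = int(np.argmax(activity))
    if params.dominance_boost != 1.0:
        activity[dom] *= params.dominance_boost
        if params.dominant_group is not None:
            groups[dom] = params.dominant_group
        # a zone-wide dominant is a broad generalist present everywhere
        breadth[dom] = max(breadth[dom], float(np.quantile(breadth, 0.9)))
    occ_plant = rng.random((P, params.n_sites)) < params.occupancy
    occ_pol = rng.random((Q, params.n_sites)) < params.occupancy
    if params.dominance_boost != 1.0:
        occ_pol[dom, :] = True
    return {
        "traits": traits, "plant_abundance": abund, "optima": optima,
        "activity": activity, "breadth": breadth, "groups": groups,
        "occ_plant": occ_plant, "occ_pol": occ_pol, "dominant": dom,
    }


def _labels(params: SynthParams, groups: np.ndarray) -> tuple[list[str], list[str]]:
    width_p = len(str(params.n_plants))
    plants = [f"plant_{i + 1:0{width_p}d}" for i in range(params.n_plants)]
    width_q = len(str(params.n_pollinators))
    pols = [f"{g}_{j + 1:0{width_q}d}" for j, g in enumerate(groups)]
    return plants, pols


def generate_zone(params: SynthParams) -> tuple[pd.DataFrame, dict]:
    """Generate one zone's specimen records plus the latent truth record."""
    rng = np.random.default_rng([params.seed, 0])
    lat = _latents(params, rng)
    plants, pols = _labels(params, lat["groups"])
    P, Q = params.n_plants, params.n_pollinators

    gap = lat["traits"][:, None] - lat["optima"][None, :]
    w = np.exp(-(gap ** 2) / (2.0 * lat["breadth"][None, :] ** 2))
    base = params.intensity * lat["plant_abundance"][:, None] * lat["activity"][None, :] * w

    frames = []
    for s in range(params.n_sites):
        mask = np.outer(lat["occ_plant"][:, s], lat["occ_pol"][:, s])
        mean = np.broadcast_to(base * mask, (params.n_periods, P, Q))
        counts = rng.poisson(mean)
        t_ix, p_ix, q_ix = np.nonzero(counts)
        reps = counts[t_ix, p_ix, q_ix]
        t_ix = np.repeat(t_ix, reps)
        p_ix = np.repeat(p_ix, reps)
        q_ix = np.repeat(q_ix, reps)
        frames.append(pd.DataFrame({
            "zone": params.zone,
            "site": f"S{s + 1}",
            "period": [f"T{t + 1}" for t in t_ix],
            "pollinator": [pols[q] for q in q_ix],
            "plant": [plants[p] for p in p_ix],
            "group": [lat["groups"][q] for q in q_ix],
            "count": 1,
        }))
    records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(records):
        records = records.sort_values(
            ["site", "period", "plant", "pollinator"], kind="stable"
        ).reset_index(drop=True)
    else:
        records = pd.DataFrame(
            columns=["zone", "site", "period", "pollinator", "plant", "group", "count"]
        )
    truth = {
        "params": dataclasses.asdict(params),
        "plants": plants,
        "pollinators": pols,
        **{k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in lat.items()},
    }
    return records, truth


def generate_flower_counts(params: SynthParams) -> pd.DataFrame:
    """Log-normal flower counts per (site, period, plant), zero where unoccupied."""
    rng = np.random.default_rng([params.seed, 1])
    lat_rng = np.random.default_rng([params.seed, 0])
    lat = _latents(params, lat_rng)  # same latents as generate_zone
    plants, _ = _labels(params, lat["groups"])
    rows = []
    for s in range(params.n_sites):
        for t in range(params.n_periods):
            flowers = rng.lognormal(params.flower_mu, params.flower_sigma, params.n_plants)
            flowers = np.rint(flowers * lat["plant_abundance"] * lat["occ_plant"][:, s]).astype(int)
            for i in range(params.n_plants):
                if flowers[i] > 0:
                    rows.append((params.zone, f"S{s + 1}", f"T{t + 1}", plants[i], int(flowers[i])))
    return pd.DataFrame(rows, columns=["zone", "site", "period", "plant", "flowers"])


def generate_dataset(params: SynthParams) -> ZoneDataset:
    records, truth = generate_zone(params)
    flowers = generate_flower_counts(params)
    return ZoneDataset(records=records, flowers=flowers, truth=truth)


def design_table(params_by_zone: Mapping[str, SynthParams]) -> pd.DataFrame:
    """Every (zone, site, period) visit declared by a set of zone parameters."""
    rows = [
        (zone, f"S{s + 1}", f"T{t + 1}")
        for zone, p in params_by_zone.items()
        for s in range(p.n_sites)
        for t in range(p.n_periods)
    ]
    return pd.DataFrame(rows, columns=["zone", "site", "period"])


# ---------------------------------------------------------------------------
# three-zone elevational preset
# ---------------------------------------------------------------------------

def gradient_params(seed: int = 0) -> dict[str, SynthParams]:
    """Parameters for a three-zone elevational gradient (PP < MC < SF).

    Mid zone richest and most abundant; high zone fewest plants with one
    numerically dominant fly; niche breadths widen with elevation so network
    specialization declines on average from PP to SF.
    """
    return {
        "PP": SynthParams(
            zone="PP", n_plants=27, n_pollinators=95,
            niche_mu=np.log(0.045), niche_sigma=0.7,
            intensity=0.038, activity_sigma=0.9,
            group_probs=(0.40, 0.48, 0.12), seed=_sub(seed, 0),
        ),
        "MC": SynthParams(
            zone="MC", n_plants=32, n_pollinators=115,
            niche_mu=np.log(0.09), niche_sigma=0.7,
            intensity=0.022, activity_sigma=0.9,
            group_probs=(0.33, 0.42, 0.25), seed=_sub(seed, 1),
        ),
        "SF": SynthParams(
            zone="SF", n_plants=20, n_pollinators=85,
            niche_mu=np.log(0.22), niche_sigma=0.7,
            intensity=0.013, activity_sigma=0.9,
            dominance_boost=3.2, dominant_group="fly",
            group_probs=(0.41, 0.33, 0.26), seed=_sub(seed, 2),
        ),
    }


def _sub(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0])


def preset_gradient(seed: int = 0) -> dict[str, ZoneDataset]:
    """Generate the full three-zone gradient dataset."""
    return {zone: generate_dataset(p) for zone, p in gradient_params(seed).items()}
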