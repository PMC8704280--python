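from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from pollnet import (
    InteractionMatrix,
    SiteNetwork,
    SynthParams,
    ZoneCollection,
    pool_zone,
    preset_gradient,
    zones_from_records,
)


@pytest.fixture
def triangular3() -> InteractionMatrix:
    return InteractionMatrix(
        ("pA", "pB", "pC"), ("iX", "iY", "iZ"), [[1, 1, 1], [1, 1, 0], [1, 0, 0]]
    )


@pytest.fixture
def uniform2() -> InteractionMatrix:
    return InteractionMatrix(("pA", "pB"), ("iX", "iY"), [[1, 1], [1, 1]])


def make_matrix(counts, prefix=("p", "i")) -> InteractionMatrix:
    counts = np.asarray(counts)
    return InteractionMatrix(
        tuple(f"{prefix[0]}{i}" for i in range(counts.shape[0])),
        tuple(f"{prefix[1]}{j}" for j in range(counts.shape[1])),
        counts,
    )


def make_zone(site_counts: dict[str, list], zone: str = "Z") -> ZoneCollection:
    sites = [SiteNetwork(zone, site, make_matrix(c).trim()) for site, c in site_counts.items()]
    return pool_zone(sites)


@pytest.fixture
def records_csv(tmp_path):
    def write(text: str, name: str = "records.csv") -> Path:
        p = tmp_path / name
        p.write_text(text)
        return p

    return write


@pytest.fixture(scope="session")
def gradient_data():
    return preset_gradient(seed=7)


@pytest.fixture(scope="session")
def gradient_zones(gradient_data):
    records = pd.concat([d.records for d in gradient_data.values()], ignore_index=True)
    return zones_from_records(records)


def small_zone_params(seed: int, niche_mu: float = np.log(0.06), **kw) -> SynthParams:
    """A fast-to-generate zone used by the statistical property tests."""
    defaults = dict(
        zone="Z", n_plants=15, n_pollinators=40, n_sites=4, n_periods=5,
        intensity=0.05, niche_mu=niche_mu, niche_sigma=0.7, seed=seed,
    )
    defaults.update(kw)
    return SynthParams(**defaults)
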