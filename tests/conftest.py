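from __future__ import annotations

import sys
from pathlib import Path

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")
sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fernplast.model import Feature, FeatureKind, Interval, Plastome
from fernplast.simulate import SimConfig, simulate_plastome


def random_dna(seed: int, n: int, gc: float = 0.38) -> str:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def toy_plastome(seed: int = 0, n: int = 2000, circular: bool = True,
                 features: list[Feature] | None = None) -> Plastome:
    return Plastome(id=f"toy{seed}", sequence=random_dna(seed, n),
                    circular=circular, features=features or [])


@pytest.fixture(scope="session")
def sim_pair():
    """One simulated 60 kb plastome shared across read-only tests."""
    cfg = SimConfig(seed=11, genome_bp=60_000, ir_bp=9_000, ssc_bp=12_000)
    return simulate_plastome(cfg)


@pytest.fixture
def tiny_annotated() -> Plastome:
    feats = [
        Feature("g1", FeatureKind.CDS, "+", [Interval(0, 100)]),
        Feature("g2", FeatureKind.TRNA, "-", [Interval(150, 250)]),
        Feature("g3", FeatureKind.RRNA, "+", [Interval(400, 700)]),
    ]
    return Plastome(id="tiny", sequence=random_dna(3, 1000), circular=True,
                    features=feats)
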