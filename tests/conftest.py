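from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from pathwayhubs import PipelineConfig, SimulationConfig
from pathwayhubs.enrichment import NESMatrix
from pathwayhubs.io_formats import RankedList


@pytest.fixture
def tiny_ranked() -> RankedList:
    return RankedList.from_pairs(
        [("g1", 4.0), ("g2", 3.0), ("g3", 2.0), ("g4", 1.0)]
    )


@pytest.fixture(scope="session")
def ranked8() -> RankedList:
    rng = np.random.default_rng(0)
    metrics = np.sort(rng.normal(size=8))[::-1]
    return RankedList.from_pairs((f"x{i}", m) for i, m in enumerate(metrics))


def make_nes_matrix(nes: dict, pvals: dict, alpha: float = 0.05) -> NESMatrix:
    """Build a small NESMatrix from column dicts (condition -> pathway values)."""
    nes_df = pd.DataFrame(nes, dtype=float)
    p_df = pd.DataFrame(pvals, dtype=float)
    return NESMatrix(nes=nes_df, nominal_p=p_df, alpha=alpha)


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """A fast gene-level study: 20 pathways × 8 conditions, 6 planted hubs."""
    return SimulationConfig(
        n_genes=500,
        n_pathways=20,
        genes_per_pathway=(10, 15),
        n_conditions=10,
        n_toxic_conditions=6,
        n_hubs_A=3,
        n_hubs_B=3,
        effect_size=3.0,
        noise_sd=1.0,
        n_replicates=3,
        background_fraction=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_pipe_config() -> PipelineConfig:
    # thresholds scaled to the 20-pathway fixture (they are config, not law)
    # p_max relaxed: at 10 conditions the published 1e-4 needs |r| ~ 0.95
    return PipelineConfig(
        n_perm=100,
        theta_hr=3,
        theta_mr=1,
        theta_resp=3,
        theta_deg=2,
        min_overlap=4,
        p_max=0.05,
        seed=42,
    )
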