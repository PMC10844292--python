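import numpy as np
import pytest

from flarekit.config import AbundanceEffect, CloneExpansion, DEEffect, SimConfig
from flarekit.simulate import simulate_study

SMALL_CLUSTERS = (
    [f"CD4_{i}" for i in range(1, 5)]
    + [f"CD8_{i}" for i in range(1, 4)]
    + ["BC_1", "BC_2", "DC_1"]
)


def small_config(**overrides) -> SimConfig:
    """A compact paired two-arm study used across the suite."""
    kwargs = dict(
        n_flare=8,
        n_dfr=6,
        cluster_ids=list(SMALL_CLUSTERS),
        cells_per_sample_mean=600.0,
        n_transcripts=40,
        n_proteins=8,
        seed=7,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def planted_config() -> SimConfig:
    return small_config(
        planted_abundance_effects=[AbundanceEffect("CD4_1", "flare", 0.9)],
        planted_de_effects=[DEEffect("CD4_2", "GENE005", "FlareV_vs_FlareB", 2.0)],
        planted_clone_expansions=[CloneExpansion("F01", "CD8", 0, 8.0)],
    )


@pytest.fixture(scope="session")
def planted_study(planted_config):
    return simulate_study(planted_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
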