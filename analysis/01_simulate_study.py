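#!/usr/bin/env python
"""Generate the synthetic DMARD-cessation study used by the downstream steps.

Design mirrors the mass-cytometry cohort: 20 flare + 16 remission patients,
paired baseline/follow-up samples, 31 clusters, ~3000 cells per sample,
transcript + surface-protein markers, and TCR/BCR repertoires. Planted
truth: +0.8 log-odds at flare onset on CD4_1, BC_1 and GDT_3 and -0.8 on
DC_2 (the published flare-associated pattern), 2-fold DE markers in CD4_1,
and one 8-fold clonal expansion per arm.
"""

from pathlib import Path

import numpy as np

from flarekit.config import (
    DEFAULT_CLUSTERS,
    AbundanceEffect,
    CloneExpansion,
    DEEffect,
    SimConfig,
    default_concentration,
)
from flarekit.io import write_study
from flarekit.simulate import simulate_study

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 1

# the flare-associated subsets of the cohort are rare (0.1-2% of cells);
# pin their mean abundances accordingly so the planted shifts move little
# total compositional mass
RARE_PCT = {"CD4_1": 0.5, "BC_1": 0.2, "GDT_3": 1.0, "DC_2": 1.5}


def _concentration() -> np.ndarray:
    alpha = default_concentration(len(DEFAULT_CLUSTERS))
    total = alpha.sum()
    for cluster, pct in RARE_PCT.items():
        alpha[DEFAULT_CLUSTERS.index(cluster)] = total * pct / 100.0
    return alpha * (total / alpha.sum())


def build_config(seed: int = SEED) -> SimConfig:
    return SimConfig(
        base_concentration=_concentration(),
        planted_abundance_effects=[
            AbundanceEffect("CD4_1", "flare", 0.8),
            AbundanceEffect("BC_1", "flare", 0.8),
            AbundanceEffect("GDT_3", "flare", 0.8),
            AbundanceEffect("DC_2", "flare", -0.8),
        ],
        planted_de_effects=[
            DEEffect("CD4_1", f"GENE{i:03d}", "FlareV_vs_FlareB", 2.0)
            for i in (1, 2, 3)
        ],
        planted_clone_expansions=[
            CloneExpansion("F01", "CD8", 0, 8.0),
            CloneExpansion("R01", "CD4", 0, 8.0),
        ],
        seed=seed,
    )


def main() -> None:
    cfg = build_config()
    study, truth = simulate_study(cfg)
    write_study(study, truth, OUT, seed=SEED)
    print(f"samples: {len(study.meta)}  cells: {len(study.assignments)}")
    print(f"chain records: {len(study.chains)}")
    print(f"planted flare-associated: {truth.true_flare_associated}")
    print(f"planted clonotypes: {len(truth.true_clonotypes)}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
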