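"""Study-design configuration for the synthetic paired two-arm generator.

The default configuration mirrors the BioRRA DMARD-cessation design: two
arms (patients who flare after drug withdrawal versus patients who stay in
drug-free remission), each patient sampled at baseline and once more at
follow-up (flare onset, or month 6 for remission patients), 31 circulating
cell clusters spanning CD4/CD8 T-cell, B-cell, dendritic-cell, gamma-delta
and NK compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

GROUPS = ("flare", "dfr")
VISITS = ("baseline", "followup")
CONTRAST_NAMES = (
    "FlareV_vs_FlareB",
    "RemV_vs_RemB",
    "FlareB_vs_RemB",
    "FlareV_vs_RemV",
)

# default 31-cluster panel; prefixes map to immune compartments
DEFAULT_CLUSTERS = (
    [f"CD4_{i}" for i in range(1, 9)]
    + [f"CD8_{i}" for i in range(1, 8)]
    + [f"BC_{i}" for i in range(1, 7)]
    + [f"DC_{i}" for i in range(1, 5)]
    + [f"GDT_{i}" for i in range(1, 4)]
    + [f"NK_{i}" for i in range(1, 4)]
)

COMPARTMENT_PREFIXES = {"CD4": "CD4", "CD8": "CD8", "BC": "B"}


def compartment_of(cluster_id: str) -> str | None:
    """Immune-receptor compartment of a cluster, or None (no V(D)J locus)."""
    prefix = str(cluster_id).split("_")[0]
    return COMPARTMENT_PREFIXES.get(prefix)


@dataclass(frozen=True)
class AbundanceEffect:
    """Planted group-by-visit composition shift for one cluster.

    ``log_odds`` is added to the cluster's log relative weight at the
    follow-up visit of every patient in ``group``.
    """

    cluster_id: str
    group: str
    log_odds: float


@dataclass(frozen=True)
class DEEffect:
    """Planted differential expression: the feature's mean is scaled by
    ``2**log2_fc`` for cells of ``cluster_id`` in the first-named arm of
    ``contrast``."""

    cluster_id: str
    feature_id: str
    contrast: str
    log2_fc: float


@dataclass(frozen=True)
class CloneExpansion:
    """Planted within-patient clonal expansion: the follow-up sampling
    weight of the clone at ``clone_rank`` (0 = largest planted clone) in
    ``compartment`` is multiplied by ``multiplier``."""

    patient_id: str
    compartment: str
    clone_rank: int
    multiplier: float


@dataclass
class SimConfig:
    """Ground-truth-bearing description of one simulated study."""

    n_flare: int = 20
    n_dfr: int = 16
    cluster_ids: Sequence[str] = field(default_factory=lambda: list(DEFAULT_CLUSTERS))
    cells_per_sample_mean: float = 3000.0
    cells_per_sample_shape: float = 8.0  # gamma shape of the Poisson rate
    base_concentration: np.ndarray | None = None  # Dirichlet alpha, len = n clusters
    planted_abundance_effects: list[AbundanceEffect] = field(default_factory=list)
    n_transcripts: int = 320
    n_proteins: int = 34
    planted_de_effects: list[DEEffect] = field(default_factory=list)
    transcript_mean: float = 0.5  # NB mean scale for transcripts
    transcript_dispersion: float = 2.0  # NB size (smaller = more dispersed)
    protein_mean: float = 5.0
    protein_sigma: float = 0.5  # log-normal sd around the cluster mean
    clone_exponent: float = 2.5  # discrete power-law exponent for clone sizes
    clonal_fraction: dict = field(
        default_factory=lambda: {"CD4": 0.113, "CD8": 0.347, "B": 0.040}
    )
    planted_clone_expansions: list[CloneExpansion] = field(default_factory=list)
    cdr3_length_range: tuple[int, int] = (30, 60)  # nt, multiples of 3
    seed: int = 0

    def __post_init__(self):
        if len(self.cluster_ids) < 2:
            raise ValueError("need at least 2 clusters")
        if self.base_concentration is None:
            self.base_concentration = default_concentration(len(self.cluster_ids))
        self.base_concentration = np.asarray(self.base_concentration, dtype=float)
        if len(self.base_concentration) != len(self.cluster_ids):
            raise ValueError("base_concentration length must match cluster_ids")
        if np.any(~np.isfinite(self.base_concentration)) or np.any(
            self.base_concentration <= 0
        ):
            raise ValueError("all Dirichlet concentrations must be finite and > 0")
        if self.cells_per_sample_mean <= 0 or self.cells_per_sample_shape <= 0:
            raise ValueError("cells-per-sample law parameters must be positive")
        known = set(self.cluster_ids)
        for eff in self.planted_abundance_effects:
            if eff.cluster_id not in known:
                raise ValueError(f"abundance effect targets unknown cluster {eff.cluster_id!r}")
            if eff.group not in GROUPS:
                raise ValueError(f"unknown group {eff.group!r}")
            if not np.isfinite(eff.log_odds):
                raise ValueError("log-odds shifts must be finite")
        for eff in self.planted_de_effects:
            if eff.cluster_id not in known:
                raise ValueError(f"DE effect targets unknown cluster {eff.cluster_id!r}")
            if eff.contrast not in CONTRAST_NAMES:
                raise ValueError(f"unknown contrast {eff.contrast!r}")
            if not np.isfinite(eff.log2_fc):
                raise ValueError("log fold changes must be finite")
        for exp_ in self.planted_clone_expansions:
            if exp_.multiplier < 1:
                raise ValueError("expansion multipliers must be >= 1")
        if self.clone_exponent <= 1:
            raise ValueError("clone-size power-law exponent must exceed 1")
        lo, hi = self.cdr3_length_range
        if lo % 3 or hi % 3 or lo < 3 or hi < lo:
            raise ValueError("CDR3 length range must be multiples of 3 with lo <= hi")

    @property
    def patient_ids(self) -> list[str]:
        return [f"F{i:02d}" for i in range(1, self.n_flare + 1)] + [
            f"R{i:02d}" for i in range(1, self.n_dfr + 1)
        ]

    def feature_ids(self) -> tuple[list[str], list[str]]:
        tx = [f"GENE{i:03d}" for i in range(1, self.n_transcripts + 1)]
        pr = [f"ADT{i:02d}" for i in range(1, self.n_proteins + 1)]
        return tx, pr

    def validate_patient(self, patient_id: str) -> None:
        if patient_id not in self.patient_ids:
            raise ValueError(f"unknown patient {patient_id!r}")


def default_concentration(n_clusters: int, total: float = 50.0) -> np.ndarray:
    """Dirichlet concentration with a gently decaying abundance profile.

    Cluster mean proportions follow k^-0.7 (a realistic mix of common and
    rare subsets: ~8% down to ~1% for 31 clusters); the total concentration
    sets the patient-to-patient compositional overdispersion.
    """
    w = np.arange(1, n_clusters + 1, dtype=float) ** -0.7
    w /= w.sum()
    return total * w


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    for key, cls in [
        ("planted_abundance_effects", AbundanceEffect),
        ("planted_de_effects", DEEffect),
        ("planted_clone_expansions", CloneExpansion),
    ]:
        if key in d:
            d[key] = [cls(**e) if isinstance(e, dict) else e for e in d[key]]
    if "cdr3_length_range" in d:
        d["cdr3_length_range"] = tuple(d["cdr3_length_range"])
    return SimConfig(**d)
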