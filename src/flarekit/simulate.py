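"""Synthetic paired two-arm single-cell studies with known ground truth.

The generator emulates the DMARD-cessation design: every patient is sampled
at baseline and follow-up, and the two samples share one latent cell-type
composition drawn from a Dirichlet prior (this single draw produces both
the sample pairing and the between-patient overdispersion that the
abundance model must absorb). Planted effects — composition shifts at
follow-up, differential markers, within-patient clonal expansions — are
recorded in a ground-truth object so every downstream test can be scored
against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GROUPS, SimConfig, compartment_of
from .expression import MarkerMatrix

__all__ = [
    "GroundTruth",
    "SimulatedStudy",
    "simulate_counts",
    "simulate_study",
    "simulate_markers",
    "simulate_repertoire",
]

# 61 sense codons: junctions are generated codon-wise so productive chains
# never translate through a stop
_SENSE_CODONS = [
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_CODON_TABLE = {
    codon: aa
    for codon, aa in zip(
        [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"],
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    )
}


def translate(junction: str) -> str:
    return "".join(
        _CODON_TABLE[junction[i : i + 3]] for i in range(0, len(junction), 3)
    )


@dataclass
class GroundTruth:
    """Planted-effect registry for one simulated study."""

    true_flare_associated: dict = field(
        default_factory=lambda: {"increase": set(), "decrease": set()}
    )
    true_de: set = field(default_factory=set)  # (cluster, feature, contrast)
    true_expanded_clones: set = field(default_factory=set)  # (patient, key)
    # realized clone membership: (patient, key) -> frozenset of cell ids,
    # only lineages that ended up with >= 2 cells (the clone definition)
    true_clonotypes: dict = field(default_factory=dict)


@dataclass
class SimulatedStudy:
    """Cell-level artifacts of one simulated study."""

    meta: pd.DataFrame  # sample_id, patient_id, group, visit
    assignments: pd.DataFrame  # cell_id, sample_id, cluster_id
    markers: MarkerMatrix | None = None
    chains: pd.DataFrame | None = None

    def __post_init__(self):
        cells = self.assignments["cell_id"]
        if cells.duplicated().any():
            raise ValueError("cell ids must be unique")
        known = set(self.meta["sample_id"])
        bad = set(self.assignments["sample_id"]) - known
        if bad:
            raise ValueError(f"assignments reference unknown samples: {sorted(bad)}")
        if self.chains is not None:
            missing = set(self.chains["cell_id"]) - set(cells)
            if missing:
                raise ValueError(
                    f"chain records reference unknown cells: {sorted(missing)[:3]}"
                )


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng([stage, config.seed])


def _build_meta(config: SimConfig) -> pd.DataFrame:
    rows = []
    for pid in config.patient_ids:
        group = "flare" if pid.startswith("F") else "dfr"
        for visit in ("baseline", "followup"):
            suffix = "B" if visit == "baseline" else "V"
            rows.append(
                {
                    "sample_id": f"{pid}_{suffix}",
                    "patient_id": pid,
                    "group": group,
                    "visit": visit,
                }
            )
    return pd.DataFrame(rows)


def simulate_counts(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample-level cluster counts without expanding to individual cells.

    Per patient one composition is drawn from Dirichlet(base_concentration)
    and shared by both visits; planted follow-up shifts multiply the
    targeted cluster's relative weight by exp(log_odds) before
    renormalisation; totals follow a gamma-Poisson (negative binomial) law.
    """
    if rng is None:
        rng = _rng(config, 1)
    meta = _build_meta(config)
    clusters = list(config.cluster_ids)
    k_index = {c: i for i, c in enumerate(clusters)}
    shifts = {g: np.zeros(len(clusters)) for g in GROUPS}
    for eff in config.planted_abundance_effects:
        shifts[eff.group][k_index[eff.cluster_id]] += eff.log_odds

    counts = np.zeros((len(meta), len(clusters)), dtype=np.int64)
    mean, shape = config.cells_per_sample_mean, config.cells_per_sample_shape
    row = 0
    for pid in config.patient_ids:
        group = "flare" if pid.startswith("F") else "dfr"
        base = rng.dirichlet(config.base_concentration)
        for visit in ("baseline", "followup"):
            p = base
            if visit == "followup" and np.any(shifts[group]):
                w = base * np.exp(shifts[group])
                p = w / w.sum()
            total = 0
            while total == 0:  # empty samples are not meaningful
                total = rng.poisson(rng.gamma(shape, mean / shape))
            counts[row] = rng.multinomial(total, p)
            row += 1
    cdf = pd.DataFrame(counts, index=meta["sample_id"], columns=clusters)
    cdf.index.name = "sample_id"
    cdf.columns.name = "cluster_id"
    return meta, cdf


def _expand_assignments(meta: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    cell_ids, sample_ids, cluster_ids = [], [], []
    for sample_id, row in counts.iterrows():
        n = int(row.sum())
        cell_ids.extend(f"{sample_id}_c{i:05d}" for i in range(n))
        sample_ids.extend([sample_id] * n)
        cluster_ids.extend(np.repeat(row.index.to_numpy(), row.to_numpy()))
    return pd.DataFrame(
        {"cell_id": cell_ids, "sample_id": sample_ids, "cluster_id": cluster_ids}
    )


def _ground_truth(config: SimConfig) -> GroundTruth:
    truth = GroundTruth()
    flare_dirs: dict[str, set] = {"increase": set(), "decrease": set()}
    dfr_affected = {
        e.cluster_id for e in config.planted_abundance_effects if e.group == "dfr"
    }
    for eff in config.planted_abundance_effects:
        if eff.group != "flare" or eff.log_odds == 0:
            continue
        if eff.cluster_id in dfr_affected:
            continue  # moves in remission patients too: not flare-associated
        flare_dirs["increase" if eff.log_odds > 0 else "decrease"].add(eff.cluster_id)
    truth.true_flare_associated = flare_dirs
    truth.true_de = {
        (e.cluster_id, e.feature_id, e.contrast) for e in config.planted_de_effects
    }
    return truth


def simulate_study(
    config: SimConfig,
    include_markers: bool = True,
    include_repertoire: bool = True,
) -> tuple[SimulatedStudy, GroundTruth]:
    """Full study: composition, cell assignments, markers and repertoire."""
    meta, counts = simulate_counts(config)
    assignments = _expand_assignments(meta, counts)
    truth = _ground_truth(config)
    markers = simulate_markers(assignments, meta, config) if include_markers else None
    chains = None
    if include_repertoire:
        chains, expanded, clone_members = simulate_repertoire(
            assignments, meta, config
        )
        truth.true_expanded_clones = expanded
        truth.true_clonotypes = {
            k: frozenset(v) for k, v in clone_members.items() if len(v) >= 2
        }
    return SimulatedStudy(meta, assignments, markers, chains), truth


def simulate_markers(
    assignments: pd.DataFrame, meta: pd.DataFrame, config: SimConfig
) -> MarkerMatrix:
    """Cell-by-feature expression with cluster structure and planted DE.

    Transcripts are negative-binomial around cluster-specific means;
    surface proteins are log-normal (continuous, right-skewed). A planted
    effect multiplies the feature's mean by 2**log2_fc for the cells of the
    targeted cluster that fall in the first-named arm of the targeted
    contrast.
    """
    from .abundance import CONTRASTS

    rng = _rng(config, 2)
    tx_ids, pr_ids = config.feature_ids()
    feature_ids = tx_ids + pr_ids
    known_features = set(feature_ids)
    for eff in config.planted_de_effects:
        if eff.feature_id not in known_features:
            raise ValueError(f"DE effect targets unknown feature {eff.feature_id!r}")
    n_tx, n_pr = len(tx_ids), len(pr_ids)
    clusters = list(config.cluster_ids)

    # cluster-specific baseline means: feature scale x cluster modulation
    tx_scale = rng.lognormal(np.log(config.transcript_mean), 1.0, n_tx)
    pr_scale = rng.lognormal(np.log(config.protein_mean), 0.7, n_pr)
    tx_mod = rng.lognormal(0.0, 0.5, (len(clusters), n_tx))
    pr_mod = rng.lognormal(0.0, 0.3, (len(clusters), n_pr))

    meta_idx = meta.set_index("sample_id")
    grp = meta_idx.loc[assignments["sample_id"], "group"].to_numpy()
    vis = meta_idx.loc[assignments["sample_id"], "visit"].to_numpy()
    clu = assignments["cluster_id"].to_numpy()

    values = np.empty((len(assignments), n_tx + n_pr), dtype=np.float32)
    feature_pos = {f: j for j, f in enumerate(feature_ids)}
    for ki, cluster in enumerate(clusters):
        sel = np.flatnonzero(clu == cluster)
        if not len(sel):
            continue
        mu_tx = np.broadcast_to(tx_scale * tx_mod[ki], (len(sel), n_tx)).copy()
        mu_pr = np.broadcast_to(pr_scale * pr_mod[ki], (len(sel), n_pr)).copy()
        for eff in config.planted_de_effects:
            if eff.cluster_id != cluster:
                continue
            g1, v1 = CONTRASTS[eff.contrast].arm1
            hit = (grp[sel] == g1) & (vis[sel] == v1)
            j = feature_pos[eff.feature_id]
            if j < n_tx:
                mu_tx[hit, j] *= 2.0 ** eff.log2_fc
            else:
                mu_pr[hit, j - n_tx] *= 2.0 ** eff.log2_fc
        size = config.transcript_dispersion
        values[sel, :n_tx] = rng.negative_binomial(size, size / (size + mu_tx))
        values[sel, n_tx:] = rng.lognormal(np.log(mu_pr), config.protein_sigma)
    return MarkerMatrix(
        values=values,
        feature_ids=feature_ids,
        feature_kind=np.array(
            ["transcript"] * n_tx + ["protein"] * n_pr, dtype=object
        ),
        cell_ids=assignments["cell_id"].tolist(),
    )


def _random_junction(rng: np.random.Generator, lo: int, hi: int) -> str:
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    idx = rng.integers(0, len(_SENSE_CODONS), n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _fresh_junction(rng, lo, hi, used: set) -> str:
    while True:
        j = _random_junction(rng, lo, hi)
        if j not in used:
            used.add(j)
            return j


_LOCI = {"CD4": ("TRA", "TRB"), "CD8": ("TRA", "TRB")}


def _loci_for(compartment: str, rng) -> tuple[str, str]:
    if compartment in _LOCI:
        return _LOCI[compartment]
    light = "IGK" if rng.random() < 0.6 else "IGL"
    return ("IGH", light)


def simulate_repertoire(
    assignments: pd.DataFrame, meta: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, set, dict]:
    """AIRR-style chain records with a heavy-tailed clonal structure.

    Per patient and receptor compartment, latent clone weights are drawn
    from a zeta law (exponent ``clone_exponent``, truncated at the number of
    cells); each cell is clonal with probability ``clonal_fraction`` and
    then picks a clone proportionally to its weight, otherwise it receives
    a fresh singleton junction pair. Planted expansions multiply a clone's
    weight at the follow-up visit. Every T cell carries exactly one
    productive TRA and TRB chain; B cells carry IGH plus one light chain.
    Returns the chain table, the ground-truth expanded (patient, clone key)
    set, and the realized clone membership map (patient, key) -> cell ids.
    """
    rng = _rng(config, 3)
    for exp_ in config.planted_clone_expansions:
        config.validate_patient(exp_.patient_id)
    meta_idx = meta.set_index("sample_id")
    patient = meta_idx.loc[assignments["sample_id"], "patient_id"].to_numpy()
    visit = meta_idx.loc[assignments["sample_id"], "visit"].to_numpy()
    comp = assignments["cluster_id"].map(compartment_of).to_numpy()
    lo, hi = config.cdr3_length_range

    records = []
    expanded_truth = set()
    clone_members: dict = {}
    for pid in config.patient_ids:
        used: set = set()
        for compartment in ("CD4", "CD8", "B"):
            sel = np.flatnonzero((patient == pid) & (comp == compartment))
            if not len(sel):
                continue
            n_cells = len(sel)
            frac = config.clonal_fraction.get(compartment, 0.0)
            # latent clone pool: zeta sizes, truncated at the cell count,
            # enough mass to cover the expected clonal cells
            sizes = []
            target = max(frac * n_cells, 1.0)
            while np.sum(sizes) < target:
                sizes.append(min(int(rng.zipf(config.clone_exponent)), n_cells))
            sizes = np.asarray(sorted(sizes, reverse=True), dtype=float)
            mult = np.ones(len(sizes))
            for exp_ in config.planted_clone_expansions:
                if exp_.patient_id == pid and exp_.compartment == compartment:
                    if exp_.clone_rank >= len(sizes):
                        raise ValueError(
                            f"expansion rank {exp_.clone_rank} exceeds clone pool "
                            f"of patient {pid!r} ({len(sizes)} clones)"
                        )
                    mult[exp_.clone_rank] *= exp_.multiplier
            loci = [_loci_for(compartment, rng) for _ in sizes]
            keys = [
                (
                    _fresh_junction(rng, lo, hi, used),
                    _fresh_junction(rng, lo, hi, used),
                )
                for _ in sizes
            ]
            for r in np.flatnonzero(mult > 1.0):
                expanded_truth.add((pid, f"{keys[r][0]}|{keys[r][1]}"))

            w_base = frac * sizes / sizes.sum()
            # expansions add clonal mass at follow-up (the expanded clone
            # displaces singletons and clones alike, pro rata)
            w_follow = frac * sizes * mult / sizes.sum()
            for visit_name, w_clone in (
                ("baseline", w_base),
                ("followup", w_follow),
            ):
                v_sel = sel[visit[sel] == visit_name]
                if not len(v_sel):
                    continue
                probs = np.r_[w_clone, 1.0 - w_base.sum()]
                probs = probs / probs.sum()
                choice = rng.choice(len(sizes) + 1, size=len(v_sel), p=probs)
                for cell_pos, c in zip(v_sel, choice):
                    cell_id = assignments["cell_id"].iat[cell_pos]
                    if c < len(sizes):
                        (l1, l2), (j1, j2) = loci[c], keys[c]
                        clone_members.setdefault(
                            (pid, f"{j1}|{j2}"), set()
                        ).add(cell_id)
                    else:
                        l1, l2 = _loci_for(compartment, rng)
                        j1 = _fresh_junction(rng, lo, hi, used)
                        j2 = _fresh_junction(rng, lo, hi, used)
                    for locus, junction in ((l1, j1), (l2, j2)):
                        records.append(
                            (
                                f"{cell_id}_{locus}",
                                cell_id,
                                locus,
                                True,
                                junction,
                                translate(junction),
                                f"{locus}V{1 + int(rng.integers(8))}-1*01",
                                f"{locus}J{1 + int(rng.integers(4))}*01",
                                1 + int(rng.integers(40)),
                            )
                        )
    chains = pd.DataFrame(
        records,
        columns=[
            "sequence_id", "cell_id", "locus", "productive", "junction",
            "junction_aa", "v_call", "j_call", "duplicate_count",
        ],
    )
    return chains, expanded_truth, clone_members
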