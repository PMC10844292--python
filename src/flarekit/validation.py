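"""Simulation studies that validate the pipeline's statistical guarantees.

Each function runs a self-contained replicated experiment at the study's
design (paired visits, Dirichlet-multinomial composition, heavy-tailed
repertoires) and returns summary rates: type-I error of the abundance mixed
model under the null, power and FDR against planted composition shifts,
Hutcheson-test calibration on same-community repertoire pairs, and recovery
of planted clonal expansions. The acceptance machinery and the analysis
drivers both run these; nothing here is fixture data.
"""

from __future__ import annotations

import numpy as np

from .abundance import test_abundance_glmm
from .config import CloneExpansion, AbundanceEffect, DEFAULT_CLUSTERS, SimConfig
from .repertoire import (
    call_clonotypes,
    clone_shift_tests,
    hutcheson_test,
    shannon_entropy,
)
from .simulate import simulate_counts, simulate_study

__all__ = [
    "glmm_null_type1_error",
    "glmm_recovery",
    "hutcheson_null_calibration",
    "expansion_recovery",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    # stable per-replicate seeds below 2**31
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def glmm_null_type1_error(
    n_reps: int = 500, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Type-I error of the mixed-model abundance test under the null.

    The study design is the mass-cytometry cohort (20 flare + 16 remission
    patients, 31 clusters, no planted effects); each replicate tests the
    flare-onset-versus-baseline contrast for every cluster. Clusters within
    a replicate share one composition draw, so the binomial reference CI
    for the pooled rejection rate uses the replicate count as n.
    """
    rejections = 0
    total = 0
    for s in _child_seeds(seed, n_reps):
        cfg = SimConfig(seed=s)
        meta, counts = simulate_counts(cfg)
        res = test_abundance_glmm(counts, meta, "FlareV_vs_FlareB")
        p = res["p"].to_numpy()
        rejections += int(np.sum(p < alpha))
        total += len(p)
    rate = rejections / total
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_reps)
    return {
        "rate": rate,
        "n_tests": total,
        "n_reps": n_reps,
        "ci_low": alpha - half,
        "ci_high": alpha + half,
    }


# three planted targets spanning common and rare clusters
RECOVERY_TARGETS = ("CD4_3", "CD8_6", "DC_2")


def glmm_recovery(
    n_reps: int = 200, seed: int = 0, shift: float = 0.7, alpha: float = 0.05
) -> dict:
    """Power/FDR of the mixed-model test against planted follow-up shifts.

    Three of 30 clusters receive a +`shift` log-odds move at flare onset in
    flare patients. A discovery is a cluster significant after BH with a
    positive effect (the planted direction); detection and FDR are scored
    against the planted set.
    """
    clusters = list(DEFAULT_CLUSTERS[:30])
    effects = [AbundanceEffect(c, "flare", shift) for c in RECOVERY_TARGETS]
    detected = {c: 0 for c in RECOVERY_TARGETS}
    fdrs = []
    all_found = 0
    for s in _child_seeds(seed, n_reps):
        cfg = SimConfig(
            cluster_ids=clusters, planted_abundance_effects=effects, seed=s
        )
        meta, counts = simulate_counts(cfg)
        res = test_abundance_glmm(counts, meta, "FlareV_vs_FlareB")
        sig = res[(res["p_adj"] < alpha) & (res["effect"] > 0)]
        found = set(sig["cluster_id"])
        for c in RECOVERY_TARGETS:
            if c in found:
                detected[c] += 1
        if set(RECOVERY_TARGETS) <= found:
            all_found += 1
        false = len(found - set(RECOVERY_TARGETS))
        fdrs.append(false / max(len(found), 1))
    return {
        "detection_rate": {c: detected[c] / n_reps for c in RECOVERY_TARGETS},
        "all_detected_rate": all_found / n_reps,
        "mean_fdr": float(np.mean(fdrs)),
        "n_reps": n_reps,
    }


def _latent_clone_pool(
    rng: np.random.Generator,
    n_cells: int,
    clonal_fraction: float = 0.347,
    exponent: float = 2.5,
) -> np.ndarray:
    """Latent species probabilities of one repertoire community: a zeta
    clone pool carrying ``clonal_fraction`` of the mass over a bed of
    singleton-scale species."""
    sizes = []
    target = clonal_fraction * n_cells
    while np.sum(sizes) < target:
        sizes.append(min(int(rng.zipf(exponent)), n_cells))
    sizes = np.asarray(sorted(sizes, reverse=True), dtype=float)
    n_rare = max(int(round(n_cells * (1 - clonal_fraction))), 1)
    pool = np.r_[sizes, np.ones(n_rare)]
    return pool / pool.sum()


def hutcheson_null_calibration(
    n_pairs: int = 1000, seed: int = 0, n_cells: int = 1000, alpha: float = 0.05
) -> dict:
    """Rejection rate of the Hutcheson entropy test on same-community pairs.

    Each pair is two independent multinomial samples of ``n_cells`` cells
    from one latent clone-size distribution — the sampling situation whose
    noise Hutcheson's variance estimates. The test is approximate; its
    rejection rate at 0.05 is expected near, not exactly at, nominal.
    """
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_pairs):
        p = _latent_clone_pool(rng, n_cells)
        c1 = rng.multinomial(n_cells, p)
        c2 = rng.multinomial(n_cells, p)
        d1 = shannon_entropy(c1[c1 > 0])
        d2 = shannon_entropy(c2[c2 > 0])
        if hutcheson_test(d1, d2).p < alpha:
            rej += 1
    return {"rate": rej / n_pairs, "n_pairs": n_pairs}


def expansion_recovery(
    n_reps: int = 200, seed: int = 0, multiplier: float = 8.0, alpha: float = 0.05
) -> dict:
    """Recovery of a planted within-patient clonal expansion.

    One patient with ~3000 CD8 cells per visit; the largest clone's
    follow-up weight is multiplied by ``multiplier``. Scores the fraction
    of replicates where the planted clone is BH-significant with direction
    = expansion, and whether the called clonotype set matches the planted
    one exactly in every replicate.
    """
    hits = 0
    exact_sets = 0
    for s in _child_seeds(seed, n_reps):
        cfg = SimConfig(
            n_flare=1,
            n_dfr=0,
            cluster_ids=["CD8_1", "CD8_2", "CD8_3"],
            cells_per_sample_mean=3000.0,
            planted_clone_expansions=[CloneExpansion("F01", "CD8", 0, multiplier)],
            seed=s,
        )
        study, truth = simulate_study(cfg, include_markers=False)
        clonotypes, percell, _ = call_clonotypes(
            study.chains, study.assignments, study.meta
        )
        called = {
            (row.patient_id, row.key): row.size for row in clonotypes.itertuples()
        }
        expected = {k: len(v) for k, v in truth.true_clonotypes.items()}
        if called == expected:
            exact_sets += 1
        shifts = clone_shift_tests(clonotypes, percell, "whole")
        idx = shifts.set_index(["patient_id", "key"])
        ok = True
        for pk in truth.true_expanded_clones:
            if pk not in idx.index:
                ok = False
                continue
            row = idx.loc[pk]
            ok = ok and row["p_adj"] < alpha and row["direction"] == "expansion"
        if ok and truth.true_expanded_clones:
            hits += 1
    return {
        "recovery_rate": hits / n_reps,
        "exact_clonotype_rate": exact_sets / n_reps,
        "n_reps": n_reps,
    }
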