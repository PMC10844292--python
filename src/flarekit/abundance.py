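"""Differential cluster-abundance testing across paired visit contrasts.

Per-sample cluster proportions are compared across the four group/visit
contrasts of the DMARD-cessation design in two modes: an overdispersed
logistic-binomial mixed model (mass-cytometry mode) and the Wilcoxon
rank-sum test on per-sample percentages (scRNAseq mode). Within each
contrast the p-values are Benjamini-Hochberg adjusted across clusters, and
the flare-association rule selects clusters that move significantly at
flare onset in flare patients while staying flat in remission patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTRAST_NAMES
from .glmm import fit_binomial_glmm

__all__ = [
    "ContrastSpec",
    "CONTRASTS",
    "resolve_contrast",
    "counts_from_assignments",
    "compute_proportions",
    "filter_small_clusters",
    "adjust_bh",
    "test_abundance_glmm",
    "test_abundance_rank",
    "call_flare_associated",
]


@dataclass(frozen=True)
class ContrastSpec:
    """One of the four visit contrasts; arms are (group, visit) pairs and the
    first-named arm carries the positive effect direction."""

    name: str
    arm1: tuple[str, str]
    arm2: tuple[str, str]
    paired: bool


CONTRASTS = {
    "FlareV_vs_FlareB": ContrastSpec(
        "FlareV_vs_FlareB", ("flare", "followup"), ("flare", "baseline"), True
    ),
    "RemV_vs_RemB": ContrastSpec(
        "RemV_vs_RemB", ("dfr", "followup"), ("dfr", "baseline"), True
    ),
    "FlareB_vs_RemB": ContrastSpec(
        "FlareB_vs_RemB", ("flare", "baseline"), ("dfr", "baseline"), False
    ),
    "FlareV_vs_RemV": ContrastSpec(
        "FlareV_vs_RemV", ("flare", "followup"), ("dfr", "followup"), False
    ),
}
assert set(CONTRASTS) == set(CONTRAST_NAMES)


def resolve_contrast(contrast) -> ContrastSpec:
    if isinstance(contrast, ContrastSpec):
        return contrast
    try:
        return CONTRASTS[contrast]
    except KeyError:
        raise ValueError(
            f"unknown contrast {contrast!r}; expected one of {sorted(CONTRASTS)}"
        ) from None


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    required = ["sample_id", "patient_id", "group", "visit"]
    for col in required:
        if col not in meta.columns:
            raise ValueError(f"sample metadata is missing column {col!r}")
    dup = meta.duplicated(subset=["patient_id", "visit"])
    if dup.any():
        bad = meta.loc[dup, "patient_id"].iloc[0]
        raise ValueError(f"patient {bad!r} has more than one sample for a visit")
    has_baseline = meta.groupby("patient_id")["visit"].apply(
        lambda v: "baseline" in set(v)
    )
    if not has_baseline.all():
        missing = has_baseline[~has_baseline].index[0]
        raise ValueError(f"patient {missing!r} has no baseline sample")
    return meta


def counts_from_assignments(
    assignments: pd.DataFrame, meta: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Sample-by-cluster cell-count matrix from a per-cell assignment table."""
    counts = pd.crosstab(assignments["sample_id"], assignments["cluster_id"])
    counts.index.name = "sample_id"
    counts.columns.name = "cluster_id"
    if meta is not None:
        counts = counts.reindex(meta["sample_id"], fill_value=0)
    return counts


def compute_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentage abundance per sample; rows sum to 100."""
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total cells")
    return 100.0 * counts.div(totals, axis=0)


def filter_small_clusters(
    assignments: pd.DataFrame, min_cells: int = 100
) -> tuple[pd.DataFrame, list[str]]:
    """Drop clusters with fewer than ``min_cells`` cells in total.

    The threshold is strict: a cluster with exactly ``min_cells`` cells is
    retained.
    """
    if assignments.empty:
        raise ValueError("assignment table is empty")
    sizes = assignments["cluster_id"].value_counts()
    dropped = sorted(sizes.index[sizes < min_cells].tolist())
    if dropped:
        kept = assignments[~assignments["cluster_id"].isin(dropped)].copy()
    else:
        kept = assignments.copy()
    return kept, dropped


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    NaN entries stay NaN and do not count toward the number of tests.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def _contrast_samples(meta: pd.DataFrame, spec: ContrastSpec):
    """Sample ids of each arm, restricted to complete pairs when paired."""
    g1, v1 = spec.arm1
    g2, v2 = spec.arm2
    s1 = meta[(meta["group"] == g1) & (meta["visit"] == v1)]
    s2 = meta[(meta["group"] == g2) & (meta["visit"] == v2)]
    if spec.paired:
        common = sorted(set(s1["patient_id"]) & set(s2["patient_id"]))
        s1 = s1[s1["patient_id"].isin(common)]
        s2 = s2[s2["patient_id"].isin(common)]
    s1 = s1.sort_values("patient_id")
    s2 = s2.sort_values("patient_id")
    return s1, s2


def _median_pcts(props: pd.DataFrame, ids1, ids2, cluster) -> tuple[float, float]:
    return (
        float(props.loc[ids1, cluster].median()),
        float(props.loc[ids2, cluster].median()),
    )


def test_abundance_glmm(
    counts: pd.DataFrame, meta: pd.DataFrame, contrast
) -> pd.DataFrame:
    """Mixed-model differential abundance for every cluster in one contrast.

    Per cluster, a logistic-binomial mixed model with a per-patient random
    intercept (pairing) and an observation-level random intercept
    (overdispersion) is fit to (cells in cluster / total cells); the Wald
    test on the contrast coefficient is two-sided and BH-adjusted across
    clusters within the contrast.
    """
    spec = resolve_contrast(contrast)
    validate_meta(meta)
    s1, s2 = _contrast_samples(meta, spec)
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError(f"contrast {spec.name} needs >=3 samples per arm")
    sub = pd.concat([s1, s2])
    ids = sub["sample_id"].tolist()
    y_all = counts.loc[ids]
    totals = y_all.sum(axis=1).to_numpy(dtype=float)
    arm1 = np.r_[np.ones(len(s1)), np.zeros(len(s2))]
    patients = sub["patient_id"].to_numpy()
    props = compute_proportions(counts)

    rows = []
    for cluster in counts.columns:
        y = y_all[cluster].to_numpy(dtype=float)
        med1, med2 = _median_pcts(props, s1["sample_id"], s2["sample_id"], cluster)
        try:
            fit = fit_binomial_glmm(y, totals, arm1, patients)
            rows.append(
                {
                    "cluster_id": cluster,
                    "contrast": spec.name,
                    "effect": fit.effect,
                    "p": fit.p,
                    "median_pct_1": med1,
                    "median_pct_2": med2,
                    "method": fit.method,
                    "converged": fit.converged,
                    "note": fit.message,
                }
            )
        except Exception as exc:  # per-cluster isolation, not a pipeline abort
            rows.append(
                {
                    "cluster_id": cluster,
                    "contrast": spec.name,
                    "effect": np.nan,
                    "p": np.nan,
                    "median_pct_1": med1,
                    "median_pct_2": med2,
                    "method": "failed",
                    "converged": False,
                    "note": str(exc),
                }
            )
    res = pd.DataFrame(rows)
    res["p_adj"] = adjust_bh(res["p"].to_numpy())
    return res[
        ["cluster_id", "contrast", "effect", "p", "p_adj",
         "median_pct_1", "median_pct_2", "method", "converged", "note"]
    ]


def test_abundance_rank(
    proportions: pd.DataFrame, meta: pd.DataFrame, contrast
) -> pd.DataFrame:
    """Rank-sum differential abundance on per-sample percentages.

    Follows the stated procedure: a rank-sum (not signed-rank) test is used
    for the paired visit contrasts as well. Exact null distribution when
    both arms have <= 10 samples and no ties; otherwise the normal
    approximation with tie correction.
    """
    spec = resolve_contrast(contrast)
    validate_meta(meta)
    s1, s2 = _contrast_samples(meta, spec)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"contrast {spec.name} needs >=2 samples per arm")

    rows = []
    for cluster in proportions.columns:
        x = proportions.loc[s1["sample_id"], cluster].to_numpy(dtype=float)
        y = proportions.loc[s2["sample_id"], cluster].to_numpy(dtype=float)
        med1, med2 = float(np.median(x)), float(np.median(y))
        xy = np.r_[x, y]
        if np.all(xy == xy[0]):
            p = 1.0
        else:
            method = "exact" if max(len(x), len(y)) <= 10 else "asymptotic"
            if method == "exact" and len(np.unique(np.r_[x, y])) < len(x) + len(y):
                method = "asymptotic"  # ties: the exact null does not apply
            p = float(
                stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
            )
        effect = float(np.log((med1 + 1e-6) / (med2 + 1e-6)))
        rows.append(
            {
                "cluster_id": cluster,
                "contrast": spec.name,
                "effect": effect,
                "p": min(p, 1.0),
                "median_pct_1": med1,
                "median_pct_2": med2,
            }
        )
    res = pd.DataFrame(rows)
    res["p_adj"] = adjust_bh(res["p"].to_numpy())
    return res[
        ["cluster_id", "contrast", "effect", "p", "p_adj",
         "median_pct_1", "median_pct_2"]
    ]


def call_flare_associated(
    flare_results: pd.DataFrame,
    dfr_results: pd.DataFrame,
    direction: str = "increase",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flare-associated cluster selection.

    A cluster is called associated iff its abundance changes significantly
    (BH-adjusted p < alpha) in the requested direction at flare onset versus
    baseline in flare patients, AND shows no significant longitudinal change
    in remission patients.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    f = flare_results.set_index("cluster_id")
    d = dfr_results.set_index("cluster_id")
    if set(f.index) != set(d.index):
        only = set(f.index) ^ set(d.index)
        raise ValueError(
            f"result sets cover different clusters: {sorted(only)}"
        )
    rows = []
    for cluster in sorted(f.index):
        eff = f.loc[cluster, "effect"]
        sig_flare = bool(f.loc[cluster, "p_adj"] < alpha) and (
            eff > 0 if direction == "increase" else eff < 0
        )
        sig_dfr = bool(d.loc[cluster, "p_adj"] < alpha)
        rows.append(
            {
                "cluster_id": cluster,
                "direction": direction,
                "significant_in_flare_contrast": sig_flare,
                "significant_in_dfr_contrast": sig_dfr,
                "associated": sig_flare and not sig_dfr,
            }
        )
    return pd.DataFrame(rows)
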