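"""Clonal repertoire analysis: clonotype calling, diversity, expansion tests.

A clonotype is an identity class of cells sharing both paired CDR3
nucleotide junctions within one patient (size >= 2 by definition; visits
are pooled). On top of the clonotype partition the module computes clonal
fractions, per-visit Shannon-entropy diversity with Hutcheson t
comparisons, two-sided Fisher exact tests of per-clone abundance shifts
between visits (whole-compartment and per-cluster scope), and the
descriptive clone-by-cluster distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import compartment_of

__all__ = [
    "pair_cells",
    "call_clonotypes",
    "clonal_fraction",
    "shannon_entropy",
    "hutcheson_test",
    "diversity_table",
    "hutcheson_comparisons",
    "test_clone_shift",
    "clone_shift_tests",
    "clone_cluster_distribution",
    "DiversityResult",
    "HutchesonTest",
]

# locus ordering inside a clonotype key; the separator never occurs in a
# nucleotide alphabet, so (AB, C) and (A, BC) cannot collide
_PRIMARY_LOCUS = {"CD4": "TRA", "CD8": "TRA", "B": "IGH"}
_SECONDARY_LOCI = {"CD4": ("TRB",), "CD8": ("TRB",), "B": ("IGK", "IGL")}
KEY_SEP = "|"


@dataclass
class DiversityResult:
    """Shannon diversity of one repertoire (all cells, singletons included)."""

    H: float  # nats
    varH: float
    S: int  # distinct junction pairs
    N: int  # cells with a complete productive pair


@dataclass
class HutchesonTest:
    """Approximate two-sample t comparison of Shannon entropies."""

    t: float
    df: float
    p: float


def pair_cells(chains: pd.DataFrame, cell_info: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Reduce chain records to one paired junction key per cell.

    ``cell_info`` carries cell_id, patient_id, visit, cluster_id and the
    derived compartment. Multiple productive chains at one locus (and the
    IGK/IGL ambiguity for B cells) are resolved by most supporting reads,
    ties broken by lexicographically smallest junction; cells without a
    complete productive pair are excluded. Both resolutions are counted in
    the returned log, never silent.
    """
    log = {"nonproductive_chains": 0, "multiplet_loci": 0, "incomplete_cells": 0}
    prod = chains[chains["productive"].astype(bool)].copy()
    log["nonproductive_chains"] = int(len(chains) - len(prod))

    info = cell_info[
        cell_info["compartment"].isin(_PRIMARY_LOCUS)
    ][["cell_id", "patient_id", "visit", "cluster_id", "compartment"]]
    prod = prod.merge(info, on="cell_id", how="inner")
    if "duplicate_count" not in prod.columns:
        prod["duplicate_count"] = 0
    prod["duplicate_count"] = prod["duplicate_count"].fillna(0)

    # best chain per (cell, locus): most reads, then smallest junction
    prod = prod.sort_values(
        ["cell_id", "locus", "duplicate_count", "junction"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    dedup = prod.drop_duplicates(["cell_id", "locus"], keep="first")
    log["multiplet_loci"] = int(len(prod) - len(dedup))

    primary_locus = dedup["compartment"].map(_PRIMARY_LOCUS)
    primary = dedup[dedup["locus"] == primary_locus]
    is_secondary = [
        row.locus in _SECONDARY_LOCI[row.compartment] for row in dedup.itertuples()
    ]
    secondary = dedup[np.asarray(is_secondary, dtype=bool)]
    # B cells with both IGK and IGL: same tie rule across the two loci
    secondary = secondary.sort_values(
        ["cell_id", "duplicate_count", "junction"],
        ascending=[True, False, True],
        kind="stable",
    )
    n_before = len(secondary)
    secondary = secondary.drop_duplicates("cell_id", keep="first")
    log["multiplet_loci"] += int(n_before - len(secondary))

    paired = primary.merge(
        secondary[["cell_id", "junction"]], on="cell_id",
        how="inner", suffixes=("_1", "_2"),
    )
    n_cells_with_chain = dedup["cell_id"].nunique()
    log["incomplete_cells"] = int(n_cells_with_chain - len(paired))
    paired = paired.sort_values("cell_id", kind="stable")
    out = pd.DataFrame(
        {
            "cell_id": paired["cell_id"].to_numpy(),
            "patient_id": paired["patient_id"].to_numpy(),
            "visit": paired["visit"].to_numpy(),
            "cluster_id": paired["cluster_id"].to_numpy(),
            "compartment": paired["compartment"].to_numpy(),
            "key": paired["junction_1"] + KEY_SEP + paired["junction_2"],
        }
    ).reset_index(drop=True)
    return out, log


def _cell_info(assignments: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    meta_idx = meta.set_index("sample_id")
    info = assignments.copy()
    info["patient_id"] = meta_idx.loc[info["sample_id"], "patient_id"].to_numpy()
    info["visit"] = meta_idx.loc[info["sample_id"], "visit"].to_numpy()
    info["compartment"] = info["cluster_id"].map(compartment_of)
    return info


def call_clonotypes(
    chains: pd.DataFrame, assignments: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Group cells into clonotypes by paired junction identity within patient.

    Returns (clonotype table, per-cell table with a ``clonal`` flag, log).
    Keys are grouped within (patient, compartment) pooling both visits;
    groups of >= 2 cells become clonotypes.
    """
    info = _cell_info(assignments, meta)
    percell, log = pair_cells(chains, info)
    if percell.empty:
        percell["clonal"] = pd.Series(dtype=bool)
        return pd.DataFrame(
            columns=["patient_id", "compartment", "key", "size",
                     "n_baseline", "n_followup"]
        ), percell, log

    sizes = percell.groupby(["patient_id", "compartment", "key"]).size()
    clonal_keys = sizes[sizes >= 2]
    idx = pd.MultiIndex.from_frame(percell[["patient_id", "compartment", "key"]])
    percell = percell.copy()
    percell["clonal"] = idx.isin(clonal_keys.index)

    rows = []
    clonal_cells = percell[percell["clonal"]]
    for (pid, compartment, key), sub in clonal_cells.groupby(
        ["patient_id", "compartment", "key"], sort=True
    ):
        rows.append(
            {
                "patient_id": pid,
                "compartment": compartment,
                "key": key,
                "size": len(sub),
                "n_baseline": int((sub["visit"] == "baseline").sum()),
                "n_followup": int((sub["visit"] == "followup").sum()),
            }
        )
    clonotypes = pd.DataFrame(
        rows,
        columns=["patient_id", "compartment", "key", "size",
                 "n_baseline", "n_followup"],
    )
    return clonotypes, percell, log


def clonal_fraction(n_clonal_cells: int, n_total_cells: int) -> float:
    """Percentage of complete-pair cells belonging to any clonotype,
    reported to one decimal."""
    if n_total_cells <= 0:
        raise ValueError("total cell count must be positive")
    if not 0 <= n_clonal_cells <= n_total_cells:
        raise ValueError("clonal cells must lie in [0, total]")
    return round(100.0 * n_clonal_cells / n_total_cells, 1)


def shannon_entropy(sizes) -> DiversityResult:
    """Shannon entropy (nats) of a repertoire given all clone sizes,
    singletons included, with Hutcheson's variance estimate

        varH = [sum p (ln p)^2 - (sum p ln p)^2] / N + (S - 1) / (2 N^2).
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("empty clone-size vector")
    if np.any(sizes < 1):
        raise ValueError("clone sizes must be >= 1")
    n = sizes.sum()
    p = sizes / n
    logp = np.log(p)
    h = float(-np.sum(p * logp))
    s = sizes.size
    if s == 1:
        return DiversityResult(0.0, 0.0, 1, int(n))
    var = float(
        (np.sum(p * logp**2) - np.sum(p * logp) ** 2) / n + (s - 1) / (2.0 * n**2)
    )
    return DiversityResult(h, max(var, 0.0), int(s), int(n))


def hutcheson_test(d1: DiversityResult, d2: DiversityResult) -> HutchesonTest:
    """Hutcheson's approximate t-test for a difference in Shannon entropy."""
    var_sum = d1.varH + d2.varH
    if var_sum == 0.0:
        return HutchesonTest(0.0, np.nan, 1.0)
    t = (d1.H - d2.H) / np.sqrt(var_sum)
    denom = d1.varH**2 / d1.N + d2.varH**2 / d2.N
    df = var_sum**2 / denom if denom > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(df) else float(
        2.0 * stats.norm.sf(abs(t))
    )
    return HutchesonTest(float(t), float(df), min(p, 1.0))


def diversity_table(percell: pd.DataFrame) -> pd.DataFrame:
    """Shannon diversity per (patient, visit, compartment), over all
    complete-pair cells (clonal or not)."""
    rows = []
    for (pid, visit, compartment), sub in percell.groupby(
        ["patient_id", "visit", "compartment"], sort=True
    ):
        d = shannon_entropy(sub["key"].value_counts().to_numpy())
        rows.append(
            {
                "patient_id": pid,
                "visit": visit,
                "compartment": compartment,
                "H": d.H,
                "varH": d.varH,
                "S": d.S,
                "N": d.N,
            }
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "visit", "compartment", "H", "varH", "S", "N"]
    )


def hutcheson_comparisons(diversity: pd.DataFrame) -> pd.DataFrame:
    """Baseline-versus-follow-up entropy comparison per patient and
    compartment, BH-adjusted across patients within each compartment."""
    from .abundance import adjust_bh

    rows = []
    for (pid, compartment), sub in diversity.groupby(
        ["patient_id", "compartment"], sort=True
    ):
        sub = sub.set_index("visit")
        if not {"baseline", "followup"}.issubset(sub.index):
            continue
        d1 = DiversityResult(
            sub.at["baseline", "H"], sub.at["baseline", "varH"],
            int(sub.at["baseline", "S"]), int(sub.at["baseline", "N"]),
        )
        d2 = DiversityResult(
            sub.at["followup", "H"], sub.at["followup", "varH"],
            int(sub.at["followup", "S"]), int(sub.at["followup", "N"]),
        )
        res = hutcheson_test(d2, d1)  # positive t = more diverse at follow-up
        rows.append(
            {
                "patient_id": pid,
                "compartment": compartment,
                "H_baseline": d1.H,
                "H_followup": d2.H,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["patient_id", "compartment", "H_baseline", "H_followup",
                 "t", "df", "p"],
    )
    if out.empty:
        out["p_adj"] = pd.Series(dtype=float)
        return out
    out["p_adj"] = np.nan
    for compartment, sub in out.groupby("compartment"):
        out.loc[sub.index, "p_adj"] = adjust_bh(sub["p"].to_numpy())
    return out


def test_clone_shift(a: int, n1: int, b: int, n2: int) -> tuple[float, str]:
    """Two-sided Fisher exact test of a clone's abundance shift between two
    visits; the 2x2 table is [[a, n1-a], [b, n2-b]] (clone vs rest at each
    visit) and two-sidedness sums all tables with probability <= observed.

    Returns (p, direction); direction is "expansion" iff b/n2 > a/n1.
    """
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("clone counts must not exceed visit totals")
    p = float(stats.fisher_exact([[a, n1 - a], [b, n2 - b]]).pvalue)
    direction = "expansion" if b * n1 > a * n2 else "contraction"
    return min(p, 1.0), direction


def clone_shift_tests(
    clonotypes: pd.DataFrame, percell: pd.DataFrame, scope: str = "whole"
) -> pd.DataFrame:
    """Fisher tests of per-clone abundance shifts between paired visits.

    scope="whole": counts are relative to all complete-pair cells of the
    patient's compartment at each visit; BH across all clones within the
    patient. scope="subset": counts restricted to one cluster; BH within
    (patient, cluster).
    """
    from .abundance import adjust_bh

    if scope not in ("whole", "subset"):
        raise ValueError("scope must be 'whole' or 'subset'")
    rows = []
    visit_counts = percell.groupby(["patient_id", "compartment", "visit"]).size()
    cluster_counts = percell.groupby(["patient_id", "cluster_id", "visit"]).size()
    member_visit = percell.groupby(["patient_id", "key", "visit"]).size()
    member_cluster = percell.groupby(
        ["patient_id", "key", "cluster_id", "visit"]
    ).size()

    def _get(series, key):
        try:
            return int(series.loc[key])
        except KeyError:
            return 0

    for clone in clonotypes.itertuples():
        pid, compartment, key = clone.patient_id, clone.compartment, clone.key
        if scope == "whole":
            n1 = _get(visit_counts, (pid, compartment, "baseline"))
            n2 = _get(visit_counts, (pid, compartment, "followup"))
            if n1 == 0 or n2 == 0:
                continue
            a = _get(member_visit, (pid, key, "baseline"))
            b = _get(member_visit, (pid, key, "followup"))
            p, direction = test_clone_shift(a, n1, b, n2)
            rows.append(
                {
                    "patient_id": pid, "compartment": compartment, "key": key,
                    "scope": "whole", "cluster_id": "",
                    "a": a, "n1": n1, "b": b, "n2": n2,
                    "p": p, "direction": direction,
                }
            )
        else:
            try:
                clusters = member_cluster.loc[pid, key].index.get_level_values(
                    "cluster_id"
                ).unique()
            except KeyError:
                continue
            for cluster in sorted(clusters):
                n1 = _get(cluster_counts, (pid, cluster, "baseline"))
                n2 = _get(cluster_counts, (pid, cluster, "followup"))
                if n1 == 0 or n2 == 0:
                    continue
                a = _get(member_cluster, (pid, key, cluster, "baseline"))
                b = _get(member_cluster, (pid, key, cluster, "followup"))
                p, direction = test_clone_shift(a, n1, b, n2)
                rows.append(
                    {
                        "patient_id": pid, "compartment": compartment, "key": key,
                        "scope": "subset", "cluster_id": cluster,
                        "a": a, "n1": n1, "b": b, "n2": n2,
                        "p": p, "direction": direction,
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=["patient_id", "compartment", "key", "scope", "cluster_id",
                 "a", "n1", "b", "n2", "p", "direction"],
    )
    if out.empty:
        out["p_adj"] = pd.Series(dtype=float)
        return out
    out["p_adj"] = np.nan
    family = ["patient_id"] if scope == "whole" else ["patient_id", "cluster_id"]
    for _, sub in out.groupby(family):
        out.loc[sub.index, "p_adj"] = adjust_bh(sub["p"].to_numpy())
    return out


def clone_cluster_distribution(percell: pd.DataFrame) -> pd.DataFrame:
    """Descriptive cross-tab: clonal versus non-clonal cells per cluster."""
    rows = []
    for cluster, sub in percell.groupby("cluster_id", sort=True):
        n_clonal = int(sub["clonal"].sum())
        n = len(sub)
        rows.append(
            {
                "cluster_id": cluster,
                "n_clonal": n_clonal,
                "n_nonclonal": n - n_clonal,
                "proportion_clonal": n_clonal / n if n else 0.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["cluster_id", "n_clonal", "n_nonclonal", "proportion_clonal"]
    )
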