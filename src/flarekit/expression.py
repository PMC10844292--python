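"""Per-cluster differential marker expression between visit/group contrasts.

Expression of every feature (transcript or surface protein) is compared
between the cells of one cluster in the two arms of a contrast with the
Wilcoxon rank-sum test. Within each (cluster, contrast) family the p-values
are Bonferroni-corrected, and a marker is called differentially expressed
only when the adjusted p is below 0.05 AND the arm-mean fold change passes
the +/-1.5 threshold (ratio > 1.5 or < 1/1.5) — the conjunction is the
significance rule, never p alone or fold change alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "MarkerMatrix",
    "fold_change",
    "test_de",
    "count_de",
]

FC_THRESHOLD = 1.5
PSEUDOCOUNT = 0.1
MIN_EXPRESSING_FRACTION = 0.05


@dataclass
class MarkerMatrix:
    """Cell-by-feature expression with a transcript/protein kind per feature."""

    values: np.ndarray | sparse.spmatrix  # cells x features, non-negative
    feature_ids: list[str]
    feature_kind: np.ndarray  # "transcript" or "protein", len = n features
    cell_ids: list[str]

    def __post_init__(self):
        self.feature_kind = np.asarray(self.feature_kind, dtype=object)
        n_cells, n_feat = self.values.shape
        if n_feat != len(self.feature_ids) or n_feat != len(self.feature_kind):
            raise ValueError("feature annotation length mismatch")
        if n_cells != len(self.cell_ids):
            raise ValueError("cell id length mismatch")
        if len(set(self.feature_ids)) != n_feat:
            raise ValueError("feature ids must be unique")
        mn = self.values.min() if not sparse.issparse(self.values) else self.values.min()
        if mn < 0:
            raise ValueError("expression values must be non-negative")

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def to_anndata(self):
        """Optional AnnData view for interoperability with scanpy workflows."""
        import anndata

        return anndata.AnnData(
            X=sparse.csr_matrix(self.values),
            obs=pd.DataFrame(index=self.cell_ids),
            var=pd.DataFrame(
                {"feature_kind": self.feature_kind}, index=self.feature_ids
            ),
        )


def fold_change(mean_a: float, mean_b: float, pseudocount: float = PSEUDOCOUNT) -> float:
    """Ratio of arm means with an additive pseudocount.

    Values > 1 indicate higher expression in the first arm. Satisfies
    ``fold_change(a, b) * fold_change(b, a) == 1`` for the same pseudocount.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    return (mean_a + pseudocount) / (mean_b + pseudocount)


def _ranksum_pvals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per feature column; exact for tiny arms."""
    n1, n2 = x.shape[0], y.shape[0]
    p = np.ones(x.shape[1])
    constant = np.array([
        np.all(col == col[0]) for col in np.vstack([x, y]).T
    ])
    method = "exact" if max(n1, n2) <= 10 else "asymptotic"
    for j in range(x.shape[1]):
        if constant[j]:
            continue  # no information: p = 1
        mj = method
        if mj == "exact" and (
            len(np.unique(np.concatenate([x[:, j], y[:, j]]))) < n1 + n2
        ):
            mj = "asymptotic"  # exact null ignores ties; fall back
        res = stats.mannwhitneyu(x[:, j], y[:, j], alternative="two-sided", method=mj)
        p[j] = res.pvalue
    return np.clip(p, 0.0, 1.0)


def test_de(
    matrix: MarkerMatrix,
    assignments: pd.DataFrame,
    meta: pd.DataFrame,
    cluster_id: str,
    contrast,
    fc_threshold: float = FC_THRESHOLD,
    pseudocount: float = PSEUDOCOUNT,
    alpha: float = 0.05,
    min_expressing_fraction: float = MIN_EXPRESSING_FRACTION,
    min_cells_per_arm: int = 10,
) -> pd.DataFrame:
    """Differential expression for one cluster and one contrast.

    Cells of the cluster are pooled within each contrast arm and compared
    feature-by-feature. Features expressed (nonzero) in fewer than
    ``min_expressing_fraction`` of the cluster's cells in both arms are not
    tested (they do not enter the Bonferroni m).
    """
    from .abundance import resolve_contrast  # late import; no cycle at module load

    spec = resolve_contrast(contrast)
    meta_idx = meta.set_index("sample_id")
    cells = assignments[assignments["cluster_id"] == cluster_id]
    if cells.empty:
        raise ValueError(f"cluster {cluster_id!r} has no cells")
    grp = meta_idx.loc[cells["sample_id"], "group"].to_numpy()
    vis = meta_idx.loc[cells["sample_id"], "visit"].to_numpy()
    g1, v1 = spec.arm1
    g2, v2 = spec.arm2
    in1 = (grp == g1) & (vis == v1)
    in2 = (grp == g2) & (vis == v2)
    if in1.sum() == 0 or in2.sum() == 0:
        raise ValueError(
            f"empty contrast arm for cluster {cluster_id!r} in {spec.name}"
        )
    if in1.sum() < min_cells_per_arm or in2.sum() < min_cells_per_arm:
        raise ValueError(
            f"cluster {cluster_id!r} has fewer than {min_cells_per_arm} cells "
            f"in a {spec.name} arm"
        )

    pos = pd.Series(np.arange(len(matrix.cell_ids)), index=matrix.cell_ids)
    rows = pos.loc[cells["cell_id"]].to_numpy()
    dense = matrix.dense()
    x = dense[rows[in1]]
    y = dense[rows[in2]]

    frac1 = (x > 0).mean(axis=0)
    frac2 = (y > 0).mean(axis=0)
    tested = (frac1 >= min_expressing_fraction) | (frac2 >= min_expressing_fraction)
    m = int(tested.sum())
    if m == 0:
        return pd.DataFrame(
            columns=["cluster_id", "contrast", "feature_id", "feature_kind",
                     "fold_change", "p", "p_adj", "significant"]
        )

    p = _ranksum_pvals(x[:, tested], y[:, tested])
    mean1 = x[:, tested].mean(axis=0)
    mean2 = y[:, tested].mean(axis=0)
    fc = (mean1 + pseudocount) / (mean2 + pseudocount)
    p_adj = np.minimum(p * m, 1.0)
    sig = (p_adj < alpha) & ((fc > fc_threshold) | (fc < 1.0 / fc_threshold))
    feat = np.asarray(matrix.feature_ids, dtype=object)[tested]
    kind = matrix.feature_kind[tested]
    return pd.DataFrame(
        {
            "cluster_id": cluster_id,
            "contrast": spec.name,
            "feature_id": feat,
            "feature_kind": kind,
            "fold_change": fc,
            "p": p,
            "p_adj": p_adj,
            "significant": sig,
        }
    )


def count_de(results: pd.DataFrame) -> pd.DataFrame:
    """Number of significant markers per (cluster, contrast), overall and by
    feature kind."""
    if results.empty:
        return pd.DataFrame(
            columns=["cluster_id", "contrast", "n_significant",
                     "n_transcript", "n_protein"]
        )
    rows = []
    for (clu, con), sub in results.groupby(["cluster_id", "contrast"], sort=True):
        sig = sub[sub["significant"]]
        rows.append(
            {
                "cluster_id": clu,
                "contrast": con,
                "n_significant": int(len(sig)),
                "n_transcript": int((sig["feature_kind"] == "transcript").sum()),
                "n_protein": int((sig["feature_kind"] == "protein").sum()),
            }
        )
    return pd.DataFrame(rows)
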