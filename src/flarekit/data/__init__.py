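"""Published reference summaries from the BioRRA DMARD-cessation cohort.

These small tables hold the study's printed cohort-level numbers (cluster
abundance test summaries and V(D)J clonal counts). They are inputs for the
flare-association selection rule and the clonal-fraction arithmetic — not
outputs of this package.
"""

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_cluster_tests", "load_clonal_counts"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_clonal_counts() -> pd.DataFrame:
    """Published clonal/total cell counts per receptor compartment."""
    return _read("biorra_clonal_counts.tsv").set_index("compartment")


def load_cluster_tests(contrast: str) -> pd.DataFrame:
    """Published abundance-test summary for one contrast, completed over
    the union of clusters published in any contrast.

    Only significant rows were published, so clusters absent from a
    contrast are coded p_adj = 1 (not significant); their effect is set to
    0. The ``effect`` column is a sign carrier derived from the published
    median percentages (positive = higher in the first-named arm).
    """
    raw = _read("biorra_cluster_tests.tsv")
    clusters = sorted(raw["cluster_id"].unique())
    sub = raw[raw["contrast"] == contrast].set_index("cluster_id")
    rows = []
    for cluster in clusters:
        if cluster in sub.index:
            m1 = float(sub.at[cluster, "median_pct_1"])
            m2 = float(sub.at[cluster, "median_pct_2"])
            rows.append(
                {
                    "cluster_id": cluster,
                    "contrast": contrast,
                    "effect": float(np.log((m1 + 1e-6) / (m2 + 1e-6))),
                    "median_pct_1": m1,
                    "median_pct_2": m2,
                    "p_adj": float(sub.at[cluster, "p_adj"]),
                }
            )
        else:
            rows.append(
                {
                    "cluster_id": cluster,
                    "contrast": contrast,
                    "effect": 0.0,
                    "median_pct_1": np.nan,
                    "median_pct_2": np.nan,
                    "p_adj": 1.0,
                }
            )
    return pd.DataFrame(rows)
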