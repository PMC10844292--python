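"""Fold change, the Bonferroni + fold-change significance rule, and DE counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flarekit.expression import MarkerMatrix, count_de, fold_change
from flarekit.expression import test_de as run_de


def _two_arm_setup(x, y, n_features=1, feature_vals=None, kinds=None):
    """One cluster whose cells split between FlareV (x rows) and FlareB (y
    rows)."""
    n1, n2 = len(x), len(y)
    meta = pd.DataFrame(
        {
            "sample_id": ["p1_V", "p1_B"],
            "patient_id": ["p1", "p1"],
            "group": ["flare", "flare"],
            "visit": ["followup", "baseline"],
        }
    )
    cells = [f"v{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    assignments = pd.DataFrame(
        {
            "cell_id": cells,
            "sample_id": ["p1_V"] * n1 + ["p1_B"] * n2,
            "cluster_id": "clu",
        }
    )
    if feature_vals is None:
        feature_vals = np.c_[np.r_[x, y]]
    matrix = MarkerMatrix(
        values=np.asarray(feature_vals, dtype=float),
        feature_ids=[f"f{j}" for j in range(feature_vals.shape[1])],
        feature_kind=kinds
        if kinds is not None
        else np.array(["transcript"] * feature_vals.shape[1], dtype=object),
        cell_ids=cells,
    )
    return matrix, assignments, meta


def test_fold_change_worked_values():
    assert fold_change(3.0, 1.0, 0.1) == pytest.approx(3.1 / 1.1)
    assert fold_change(2.0, 2.0) == 1.0
    assert fold_change(0.0, 0.0) == 1.0
    with pytest.raises(ValueError):
        fold_change(-1.0, 2.0)


@given(
    st.floats(0, 1e4, allow_nan=False),
    st.floats(0, 1e4, allow_nan=False),
    st.floats(1e-3, 10, allow_nan=False),
)
@settings(deadline=None)
def test_fold_change_reciprocal_identity(a, b, pc):
    assert fold_change(a, b, pc) * fold_change(b, a, pc) == pytest.approx(1.0)
    assert fold_change(a, a, pc) == pytest.approx(1.0)


def test_identical_arms_not_significant():
    vals = np.tile(np.arange(1.0, 21.0)[:, None], (2, 1))
    matrix, assignments, meta = _two_arm_setup(
        np.arange(20), np.arange(20), feature_vals=vals
    )
    res = run_de(matrix, assignments, meta, "clu", "FlareV_vs_FlareB")
    assert res.loc[0, "fold_change"] == pytest.approx(1.0)
    assert not res.loc[0, "significant"]


def test_all_zero_feature_under_pseudocount_rule():
    vals = np.zeros((40, 1))
    matrix, assignments, meta = _two_arm_setup(
        np.arange(20), np.arange(20), feature_vals=vals
    )
    # the dead feature is excluded from testing by the expression filter;
    # forcing it through (threshold 0) yields the degenerate contract
    res = run_de(
        matrix, assignments, meta, "clu", "FlareV_vs_FlareB",
        min_expressing_fraction=0.0,
    )
    assert res.loc[0, "fold_change"] == 1.0
    assert res.loc[0, "p"] == 1.0
    assert not res.loc[0, "significant"]


def test_small_arms_can_never_clear_bonferroni():
    # 5 vs 5 distinct values: the exact two-sided floor is 2/C(10,5);
    # with m = 320 features no adjusted p can fall below 0.05
    rng = np.random.default_rng(0)
    vals = rng.lognormal(0, 1, size=(10, 320)) + rng.uniform(0, 1e-6, (10, 320))
    matrix, assignments, meta = _two_arm_setup(
        np.arange(5), np.arange(5), feature_vals=vals
    )
    res = run_de(
        matrix, assignments, meta, "clu", "FlareV_vs_FlareB",
        min_cells_per_arm=2, min_expressing_fraction=0.0,
    )
    floor = 2 / 252  # 2 / C(10,5)
    assert res["p"].min() >= floor - 1e-12
    assert not res["significant"].any()
    assert (res["p_adj"] >= min(floor * 320, 1.0) - 1e-9).all()


def test_planted_fold_change_recovered():
    # planted 4-fold shift on 200 vs 200 cells: fold-change estimate within
    # +-25% of 4 and the feature is flagged
    rng = np.random.default_rng(3)
    n = 200
    base = rng.negative_binomial(2, 2 / (2 + 5.0), size=(2 * n, 3)).astype(float)
    base[:n, 0] = rng.negative_binomial(2, 2 / (2 + 20.0), size=n)  # 4x mean
    matrix, assignments, meta = _two_arm_setup(
        np.arange(n), np.arange(n), feature_vals=base
    )
    res = run_de(matrix, assignments, meta, "clu", "FlareV_vs_FlareB")
    hit = res.set_index("feature_id").loc["f0"]
    assert hit["fold_change"] == pytest.approx(4.0, rel=0.25)
    assert hit["significant"]
    assert not res.set_index("feature_id").loc[["f1", "f2"], "significant"].any()


def test_rank_p_invariant_under_monotone_transform():
    rng = np.random.default_rng(4)
    vals = rng.lognormal(0, 1, size=(60, 2))
    vals[:, 1] = np.exp(vals[:, 0])  # strictly monotone transform of f0
    matrix, assignments, meta = _two_arm_setup(
        np.arange(30), np.arange(30), feature_vals=vals
    )
    res = run_de(matrix, assignments, meta, "clu", "FlareV_vs_FlareB")
    assert res.loc[0, "p"] == pytest.approx(res.loc[1, "p"], abs=1e-12)


def test_significance_is_conjunction_only():
    # strong rank separation but fold change inside (1/1.5, 1.5): never called
    n = 150
    x = np.full(n, 1.20)
    y = np.full(n, 1.00)
    vals = np.r_[x, y][:, None] + np.linspace(0, 1e-3, 2 * n)[:, None]
    matrix, assignments, meta = _two_arm_setup(
        np.arange(n), np.arange(n), feature_vals=vals
    )
    res = run_de(matrix, assignments, meta, "clu", "FlareV_vs_FlareB")
    assert res.loc[0, "p_adj"] < 0.05
    assert 1 / 1.5 < res.loc[0, "fold_change"] < 1.5
    assert not res.loc[0, "significant"]


def test_bonferroni_dominates_bh_elementwise(rng):
    from flarekit.abundance import adjust_bh

    p = rng.uniform(0, 1, 50)
    bonf = np.minimum(p * len(p), 1.0)
    assert np.all(bonf >= adjust_bh(p) - 1e-12)


def test_count_de_tallies_by_kind():
    res = pd.DataFrame(
        {
            "cluster_id": ["c1"] * 6 + ["c2"] * 4,
            "contrast": "FlareV_vs_FlareB",
            "feature_id": [f"f{i}" for i in range(10)],
            "feature_kind": ["transcript", "protein"] * 5,
            "fold_change": 2.0,
            "p": 0.001,
            "p_adj": [0.01, 0.2, 0.01, 0.01, 0.2, 0.2, 0.2, 0.2, 0.2, 0.01],
            "significant": [True, False, True, True, False, False,
                            False, False, False, True],
        }
    )
    summary = count_de(res).set_index("cluster_id")
    assert summary.loc["c1", "n_significant"] == 3
    assert summary.loc["c1", "n_transcript"] == 2
    assert summary.loc["c1", "n_protein"] == 1
    assert summary.loc["c2", "n_significant"] == 1
    assert count_de(pd.DataFrame()).empty


def test_empty_arm_is_an_error():
    matrix, assignments, meta = _two_arm_setup(np.arange(20), np.arange(20))
    meta_bad = meta.assign(visit=["followup", "followup"])
    with pytest.raises(ValueError):
        run_de(matrix, assignments, meta_bad, "clu", "FlareV_vs_FlareB")
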