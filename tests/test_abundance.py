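"""Proportions, the small-cluster filter, BH, rank tests, and the
flare-association rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flarekit.abundance import (
    adjust_bh,
    call_flare_associated,
    compute_proportions,
    counts_from_assignments,
    filter_small_clusters,
    )
from flarekit.abundance import test_abundance_rank as rank_abundance
from flarekit.data import load_cluster_tests

from oracles import bh_step_up, ranksum_two_sided


# ---------------------------------------------------------------- proportions
def test_proportions_basic_cases():
    counts = pd.DataFrame(
        [[1, 1, 1, 1], [0, 10, 0, 0]],
        index=["s1", "s2"], columns=list("abcd"),
    )
    props = compute_proportions(counts)
    assert props.loc["s1"].tolist() == [25.0] * 4
    assert props.loc["s2"].tolist() == [0.0, 100.0, 0.0, 0.0]


def test_proportions_rows_sum_to_100(rng):
    for _ in range(100):
        counts = pd.DataFrame(rng.integers(0, 50, size=(50, 31)) + 1)
        assert np.allclose(compute_proportions(counts).sum(axis=1), 100.0, atol=1e-9)


def test_zero_total_sample_is_named():
    counts = pd.DataFrame([[0, 0], [1, 2]], index=["bad", "ok"], columns=["a", "b"])
    with pytest.raises(ValueError, match="bad"):
        compute_proportions(counts)


# ------------------------------------------------------------------- filter
@pytest.mark.parametrize(
    "n_cells,kept", [(99, False), (100, True), (101, True)]
)
def test_small_cluster_threshold_is_strict(n_cells, kept):
    assignments = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells + 200)],
            "sample_id": "s1",
            "cluster_id": ["small"] * n_cells + ["big"] * 200,
        }
    )
    filtered, dropped = filter_small_clusters(assignments, min_cells=100)
    assert ("small" in dropped) == (not kept)
    assert ("small" in set(filtered["cluster_id"])) == kept


def test_min_cells_zero_is_identity():
    assignments = pd.DataFrame(
        {"cell_id": ["c1", "c2"], "sample_id": "s", "cluster_id": ["a", "b"]}
    )
    filtered, dropped = filter_small_clusters(assignments, min_cells=0)
    assert dropped == []
    pd.testing.assert_frame_equal(filtered, assignments)


# ----------------------------------------------------------------------- BH
def test_bh_hand_worked_example():
    out = adjust_bh([0.01, 0.04, 0.03, 0.05])
    assert np.allclose(out, [0.04, 0.05, 0.05, 0.05])


def test_bh_identities():
    assert adjust_bh([0.2]).tolist() == [0.2]
    assert np.allclose(adjust_bh([0.3, 0.3, 0.3]), 0.3)


def test_bh_nan_handling():
    out = adjust_bh([0.01, np.nan, 0.02])
    assert np.isnan(out[1])
    # NaN does not count toward m
    assert np.allclose(out[[0, 2]], adjust_bh([0.01, 0.02]))


@given(
    st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1,
             max_size=40)
)
@settings(deadline=None, max_examples=200)
def test_bh_matches_textbook_step_up_and_statsmodels(pvals):
    ours = adjust_bh(pvals)
    assert np.allclose(ours, bh_step_up(pvals))
    from statsmodels.stats.multitest import multipletests

    theirs = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(ours, theirs)
    # monotone in the raw p within the family, never above 1
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(ours[order]) >= -1e-12)
    assert np.all(ours <= 1.0)


# ------------------------------------------------------------------ rank test
def _meta_two_arms(n1, n2):
    rows = []
    for i in range(n1):
        rows.append((f"f{i}_B", f"f{i}", "flare", "baseline"))
        rows.append((f"f{i}_V", f"f{i}", "flare", "followup"))
    for i in range(n2):
        rows.append((f"r{i}_B", f"r{i}", "dfr", "baseline"))
        rows.append((f"r{i}_V", f"r{i}", "dfr", "followup"))
    return pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "group", "visit"]
    )


def _props_from_values(meta, baseline_vals, followup_vals, group="flare"):
    props = pd.DataFrame(
        {"clu": np.zeros(len(meta))}, index=meta["sample_id"]
    )
    sub = meta[meta["group"] == group]
    b_ids = sub.loc[sub["visit"] == "baseline", "sample_id"]
    v_ids = sub.loc[sub["visit"] == "followup", "sample_id"]
    props.loc[b_ids, "clu"] = baseline_vals
    props.loc[v_ids, "clu"] = followup_vals
    return props


def test_rank_exact_small_example():
    # arms (4,5,6) vs (1,2,3): the most extreme of C(6,3)=20 assignments,
    # exact two-sided p = 2/20 = 0.1
    meta = _meta_two_arms(3, 2)
    props = _props_from_values(meta, [1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    res = rank_abundance(props, meta, "FlareV_vs_FlareB")
    assert res.loc[0, "p"] == pytest.approx(0.1)
    assert res.loc[0, "effect"] > 0


def test_rank_identical_multisets_give_p_one():
    meta = _meta_two_arms(4, 2)
    props = _props_from_values(meta, [1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0])
    res = rank_abundance(props, meta, "FlareV_vs_FlareB")
    assert res.loc[0, "p"] == 1.0


def test_rank_min_achievable_p_eight_vs_eight(rng):
    # Table-2-like paired design: 8 + 8 samples as two arms; the floor of
    # the exact two-sided p is 2/C(16,8)
    meta = _meta_two_arms(8, 2)
    props = _props_from_values(
        meta, np.arange(1.0, 9.0), np.arange(101.0, 109.0)
    )
    res = rank_abundance(props, meta, "FlareV_vs_FlareB")
    from math import comb

    assert res.loc[0, "p"] == pytest.approx(2 / comb(16, 8))


@given(st.data())
@settings(deadline=None, max_examples=30)
def test_rank_exact_matches_enumeration_oracle(data):
    # combined n <= 12, unequal arms via the unpaired baseline contrast
    n1 = data.draw(st.integers(2, 6))
    n2 = data.draw(st.integers(2, 6))
    vals = data.draw(
        st.lists(
            st.integers(0, 10_000), min_size=n1 + n2, max_size=n1 + n2,
            unique=True,
        )
    )
    x = [v + 0.5 for v in vals[:n1]]  # flare baselines
    y = [v + 0.5 for v in vals[n1:]]  # remission baselines
    meta = _meta_two_arms(n1, n2)
    props = pd.DataFrame({"clu": 0.0}, index=meta["sample_id"])
    flare_b = meta[(meta["group"] == "flare") & (meta["visit"] == "baseline")]
    rem_b = meta[(meta["group"] == "dfr") & (meta["visit"] == "baseline")]
    props.loc[flare_b["sample_id"], "clu"] = x
    props.loc[rem_b["sample_id"], "clu"] = y
    res = rank_abundance(props, meta, "FlareB_vs_RemB")
    assert res.loc[0, "p"] == pytest.approx(ranksum_two_sided(x, y), abs=1e-12)


# ------------------------------------------------------- flare association
def test_flare_rule_on_published_tables():
    flare = load_cluster_tests("FlareV_vs_FlareB")
    dfr = load_cluster_tests("RemV_vs_RemB")
    up = call_flare_associated(flare, dfr, "increase")
    down = call_flare_associated(flare, dfr, "decrease")
    assert set(up.loc[up["associated"], "cluster_id"]) == {"CD4_1", "BC_1", "GDT_3"}
    assert set(down.loc[down["associated"], "cluster_id"]) == {"DC_2"}


def test_flare_rule_null_and_order_invariance():
    clusters = [f"c{i}" for i in range(6)]
    base = pd.DataFrame(
        {"cluster_id": clusters, "effect": 1.0, "p_adj": 1.0}
    )
    calls = call_flare_associated(base, base, "increase")
    assert not calls["associated"].any()

    flare = pd.DataFrame(
        {"cluster_id": clusters, "effect": [1, -1, 1, 1, -1, 1],
         "p_adj": [0.01, 0.01, 0.2, 0.01, 0.2, 0.04]}
    )
    dfr = pd.DataFrame(
        {"cluster_id": clusters, "effect": 1.0,
         "p_adj": [0.9, 0.9, 0.9, 0.01, 0.9, 0.9]}
    )
    expected = {"c0", "c5"}
    calls = call_flare_associated(flare, dfr, "increase")
    assert set(calls.loc[calls["associated"], "cluster_id"]) == expected
    # shuffling rows changes nothing
    calls2 = call_flare_associated(
        flare.sample(frac=1, random_state=1), dfr.sample(frac=1, random_state=2),
        "increase",
    )
    assert set(calls2.loc[calls2["associated"], "cluster_id"]) == expected


def test_flare_rule_requires_matching_clusters():
    a = pd.DataFrame({"cluster_id": ["x"], "effect": [1.0], "p_adj": [0.01]})
    b = pd.DataFrame({"cluster_id": ["y"], "effect": [1.0], "p_adj": [0.5]})
    with pytest.raises(ValueError, match="different clusters"):
        call_flare_associated(a, b)


# ------------------------------------------------------------- integration
def test_counts_from_assignments_round_trip(planted_study):
    study, _ = planted_study
    counts = counts_from_assignments(study.assignments, study.meta)
    assert int(counts.to_numpy().sum()) == len(study.assignments)
    assert list(counts.index) == list(study.meta["sample_id"])
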