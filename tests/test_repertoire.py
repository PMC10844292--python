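"""Clonotype calling, diversity, Hutcheson and Fisher kernels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flarekit.repertoire import (
    DiversityResult,
    call_clonotypes,
    clonal_fraction,
    clone_cluster_distribution,
    clone_shift_tests,
    diversity_table,
    hutcheson_comparisons,
    hutcheson_test,
    pair_cells,
    shannon_entropy,
)
from flarekit.repertoire import test_clone_shift as fisher_shift
from flarekit.simulate import simulate_study

from conftest import small_config
from oracles import fisher_two_sided, shannon_brute


def _chain(cell, locus, junction, dup=1, productive=True):
    return {
        "sequence_id": f"{cell}_{locus}_{junction[:4]}",
        "cell_id": cell,
        "locus": locus,
        "productive": productive,
        "junction": junction,
        "junction_aa": "X" * (len(junction) // 3),
        "v_call": f"{locus}V1-1*01",
        "j_call": f"{locus}J1*01",
        "duplicate_count": dup,
    }


def _setup(chain_rows, cells):
    """cells: list of (cell_id, patient, cluster)."""
    chains = pd.DataFrame(chain_rows)
    meta_rows, assign_rows = [], []
    seen = set()
    for cell, patient, cluster in cells:
        for visit, suffix in (("baseline", "B"), ("followup", "V")):
            sid = f"{patient}_{suffix}"
            if sid not in seen:
                seen.add(sid)
                meta_rows.append((sid, patient, "flare", visit))
        assign_rows.append((cell, f"{patient}_B", cluster))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "patient_id", "group", "visit"]
    )
    assignments = pd.DataFrame(
        assign_rows, columns=["cell_id", "sample_id", "cluster_id"]
    )
    return chains, assignments, meta


# ------------------------------------------------------------ clonotype calls
def test_clone_scoped_within_patient():
    # 3 cells share TRA+TRB in patient A; the same pair in patient B is not
    # part of that clone
    ja, jb = "TGT" * 10, "GCA" * 10
    rows = []
    for cell in ("a1", "a2", "a3", "b1"):
        rows += [_chain(cell, "TRA", ja), _chain(cell, "TRB", jb)]
    chains, assignments, meta = _setup(
        rows, [("a1", "pA", "CD8_1"), ("a2", "pA", "CD8_1"),
               ("a3", "pA", "CD8_2"), ("b1", "pB", "CD8_1")],
    )
    clonotypes, percell, _ = call_clonotypes(chains, assignments, meta)
    assert len(clonotypes) == 1
    assert clonotypes.loc[0, "patient_id"] == "pA"
    assert clonotypes.loc[0, "size"] == 3
    flags = percell.set_index("cell_id")["clonal"]
    assert flags["a1"] and flags["a2"] and flags["a3"]
    assert not flags["b1"]


def test_paired_key_requires_both_junctions():
    jb = "GCA" * 10
    rows = [
        _chain("c1", "TRA", "TGT" * 10), _chain("c1", "TRB", jb),
        _chain("c2", "TRA", "AAA" * 10), _chain("c2", "TRB", jb),
    ]
    chains, assignments, meta = _setup(
        rows, [("c1", "pA", "CD8_1"), ("c2", "pA", "CD8_1")]
    )
    clonotypes, _, _ = call_clonotypes(chains, assignments, meta)
    assert clonotypes.empty


def test_duplicate_chains_resolved_by_reads_then_junction():
    ja, jb = "TGT" * 10, "GCA" * 10
    rows = [
        _chain("c1", "TRA", ja, dup=5),
        _chain("c1", "TRA", "AAA" * 10, dup=2),  # fewer reads: dropped
        _chain("c1", "TRB", jb),
        _chain("c2", "TRA", ja, dup=3),
        _chain("c2", "TRA", "AAA" * 10, dup=3),  # tie: lexicographic, AAA wins
        _chain("c2", "TRB", jb),
    ]
    chains, assignments, meta = _setup(
        rows, [("c1", "pA", "CD8_1"), ("c2", "pA", "CD8_1")]
    )
    _, percell, log = call_clonotypes(chains, assignments, meta)
    keys = percell.set_index("cell_id")["key"]
    assert keys["c1"] == f"{ja}|{jb}"
    assert keys["c2"] == f"{'AAA' * 10}|{jb}"
    assert log["multiplet_loci"] == 2


def test_b_cell_light_chain_rule_and_incomplete_cells():
    jh, jk, jl = "TGT" * 10, "GCA" * 10, "CCA" * 10
    rows = [
        _chain("b1", "IGH", jh), _chain("b1", "IGK", jk, dup=2),
        _chain("b1", "IGL", jl, dup=7),  # heavier light chain wins
        _chain("b2", "IGH", jh),  # no light chain: incomplete
        _chain("b3", "IGH", jh, productive=False), _chain("b3", "IGK", jk),
    ]
    chains, assignments, meta = _setup(
        rows, [("b1", "pA", "BC_1"), ("b2", "pA", "BC_1"), ("b3", "pA", "BC_1")]
    )
    _, percell, log = call_clonotypes(chains, assignments, meta)
    assert percell.set_index("cell_id")["key"]["b1"] == f"{jh}|{jl}"
    assert "b2" not in set(percell["cell_id"])
    assert "b3" not in set(percell["cell_id"])
    assert log["incomplete_cells"] == 2
    assert log["nonproductive_chains"] == 1


def test_simulated_clonotypes_recovered_exactly(planted_study):
    study, truth = planted_study
    clonotypes, percell, _ = call_clonotypes(
        study.chains, study.assignments, study.meta
    )
    called = {
        (row.patient_id, row.key): frozenset(
            percell.loc[
                (percell["patient_id"] == row.patient_id)
                & (percell["key"] == row.key),
                "cell_id",
            ]
        )
        for row in clonotypes.itertuples()
    }
    assert called == truth.true_clonotypes


# ------------------------------------------------------------------ fractions
def test_clonal_fraction_published_arithmetic():
    assert clonal_fraction(4618, 40783) == 11.3
    assert clonal_fraction(8850, 25520) == 34.7
    assert clonal_fraction(618, 15302) == 4.0
    assert clonal_fraction(0, 100) == 0.0
    with pytest.raises(ValueError):
        clonal_fraction(1, 0)


# ------------------------------------------------------------------ diversity
def test_entropy_analytic_cases():
    uniform = shannon_entropy([2, 2, 2, 2])
    assert uniform.H == pytest.approx(np.log(4))
    single = shannon_entropy([17])
    assert single.H == 0.0 and single.varH == 0.0
    with pytest.raises(ValueError):
        shannon_entropy([])


def test_entropy_matches_brute_force():
    sizes = [5, 3, 2]
    d = shannon_entropy(sizes)
    h, var = shannon_brute(sizes)
    assert d.H == pytest.approx(h, abs=1e-12)
    assert d.varH == pytest.approx(var, abs=1e-12)
    assert d.S == 3 and d.N == 10


@given(st.lists(st.integers(1, 50), min_size=1, max_size=30))
@settings(deadline=None)
def test_entropy_invariants(sizes):
    d = shannon_entropy(sizes)
    assert -1e-12 <= d.H <= np.log(d.S) + 1e-12
    assert d.varH >= 0
    assert d.S <= d.N
    # permutation invariance
    d2 = shannon_entropy(sorted(sizes, reverse=True))
    assert d.H == pytest.approx(d2.H)


def test_hutcheson_symmetry_and_null():
    d1 = shannon_entropy([5, 3, 2, 1, 1])
    d2 = shannon_entropy([4, 4, 2, 2])
    r12 = hutcheson_test(d1, d2)
    r21 = hutcheson_test(d2, d1)
    assert r12.t == pytest.approx(-r21.t)
    assert r12.p == pytest.approx(r21.p)
    same = hutcheson_test(d1, d1)
    assert same.t == 0.0 and same.p == 1.0
    degenerate = hutcheson_test(shannon_entropy([9]), shannon_entropy([4]))
    assert degenerate.p == 1.0  # both entropies zero, varH sum zero


def test_hutcheson_large_separation_rejects():
    rng = np.random.default_rng(8)
    flat = shannon_entropy(np.full(200, 2))  # H = ln 200
    skew = shannon_entropy(np.r_[np.full(5, 300), np.ones(20)])
    res = hutcheson_test(flat, skew)
    se = np.sqrt(flat.varH + skew.varH)
    assert abs(flat.H - skew.H) > 5 * se
    assert res.p < 0.001


# ---------------------------------------------------------------- Fisher test
def test_fisher_no_shift_gives_p_one():
    p, direction = fisher_shift(5, 100, 5, 100)
    assert p == 1.0
    assert direction == "contraction"  # equal shares: not an expansion


def test_fisher_worked_table():
    p, direction = fisher_shift(3, 100, 30, 100)
    assert direction == "expansion"
    assert p == pytest.approx(fisher_two_sided(3, 100, 30, 100), abs=1e-12)


@given(st.data())
@settings(deadline=None, max_examples=150)
def test_fisher_matches_enumeration_oracle(data):
    n1 = data.draw(st.integers(1, 100))
    n2 = data.draw(st.integers(1, 100))
    a = data.draw(st.integers(0, n1))
    b = data.draw(st.integers(0, n2))
    p, _ = fisher_shift(a, n1, b, n2)
    assert p == pytest.approx(fisher_two_sided(a, n1, b, n2), abs=1e-10)
    # symmetric under swapping visits and under swapping clone/rest rows
    p_swap, _ = fisher_shift(b, n2, a, n1)
    p_comp, _ = fisher_shift(n1 - a, n1, n2 - b, n2)
    assert p == pytest.approx(p_swap, abs=1e-10)
    assert p == pytest.approx(p_comp, abs=1e-10)


def test_fisher_count_contract():
    with pytest.raises(ValueError):
        fisher_shift(5, 4, 0, 10)


# -------------------------------------------------------------- integrations
def test_expansion_recovered_with_direction(planted_study):
    study, truth = planted_study
    clonotypes, percell, _ = call_clonotypes(
        study.chains, study.assignments, study.meta
    )
    shifts = clone_shift_tests(clonotypes, percell, "whole")
    shifts = shifts.set_index(["patient_id", "key"])
    for pid, key in truth.true_expanded_clones:
        assert shifts.loc[(pid, key), "direction"] == "expansion"


def test_clone_cluster_distribution_cases(planted_study):
    study, _ = planted_study
    _, percell, _ = call_clonotypes(study.chains, study.assignments, study.meta)
    dist = clone_cluster_distribution(percell)
    merged = dist.set_index("cluster_id")
    back = percell.groupby("cluster_id")["clonal"].sum()
    for cluster, n in back.items():
        assert merged.loc[cluster, "n_clonal"] == n
    none = clone_cluster_distribution(percell.assign(clonal=False))
    assert (none["n_clonal"] == 0).all()
    allc = clone_cluster_distribution(percell.assign(clonal=True))
    assert (allc["proportion_clonal"] == 1.0).all()


def test_diversity_and_hutcheson_tables(planted_study):
    study, _ = planted_study
    _, percell, _ = call_clonotypes(study.chains, study.assignments, study.meta)
    div = diversity_table(percell)
    assert (div["H"] >= 0).all()
    assert (div["S"] <= div["N"]).all()
    comps = hutcheson_comparisons(div)
    assert ((comps["p_adj"] >= comps["p"]) | comps["p"].isna()).all()
    assert comps["p"].between(0, 1).all()
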