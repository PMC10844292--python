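"""End-to-end orchestration: simulate (or load) -> abundance -> expression
-> repertoire -> report, reproducibly from one configuration."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .abundance import (
    CONTRASTS,
    call_flare_associated,
    compute_proportions,
    counts_from_assignments,
    filter_small_clusters,
    test_abundance_glmm,
    test_abundance_rank,
    validate_meta,
)
from .config import SimConfig, sim_config_from_dict
from .expression import count_de, test_de
from .repertoire import (
    call_clonotypes,
    clonal_fraction,
    clone_cluster_distribution,
    clone_shift_tests,
    diversity_table,
    hutcheson_comparisons,
)
from .simulate import simulate_study

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """One reproducible analysis run.

    Inputs come either from ``sim`` (a SimConfig; the study is generated)
    or from ``input_dir`` (a directory in the synthetic schema: meta.tsv,
    assignments.tsv, markers/, chains.airr.tsv).
    """

    outdir: str
    sim: SimConfig | None = None
    input_dir: str | None = None
    mode: str = "glmm"  # abundance engine: "glmm" or "rank"
    alpha: float = 0.05
    min_cells: int = 100
    fc_threshold: float = 1.5
    pseudocount: float = 0.1
    min_expressing_fraction: float = 0.05
    run_expression: bool = True
    run_repertoire: bool = True
    seed: int = 0

    def __post_init__(self):
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("provide exactly one of sim= or input_dir=")
        if self.mode not in ("glmm", "rank"):
            raise ValueError("mode must be 'glmm' or 'rank'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_cells < 0 or self.fc_threshold <= 1 or self.pseudocount < 0:
            raise ValueError("invalid thresholds")

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "RunConfig":
        from .config import load_yaml

        d = load_yaml(path)
        if "sim" in d and d["sim"] is not None:
            sim = dict(d["sim"])
            if seed is not None:
                sim["seed"] = seed
            d["sim"] = sim_config_from_dict(sim)
        if outdir is not None:
            d["outdir"] = outdir
        if seed is not None:
            d["seed"] = seed
        return cls(**d)


@dataclass
class RunReport:
    """Headline numbers of one run; every entry mirrors a written TSV."""

    seed: int
    config_hash: str
    n_samples: int = 0
    n_cells: int = 0
    dropped_clusters: list = field(default_factory=list)
    flare_associated: dict = field(default_factory=dict)
    n_de_markers: dict = field(default_factory=dict)
    clonal_fractions: dict = field(default_factory=dict)
    significant_clone_shifts: dict = field(default_factory=dict)
    excluded_cells: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        study, truth = simulate_study(
            config.sim,
            include_markers=config.run_expression,
            include_repertoire=config.run_repertoire,
        )
        return study.meta, study.assignments, study.markers, study.chains, truth
    d = Path(config.input_dir)
    meta = io.read_meta(d / "meta.tsv")
    assignments = io.read_assignments(d / "assignments.tsv")
    markers = (
        io.read_markers(d / "markers")
        if config.run_expression and (d / "markers").exists()
        else None
    )
    chains = None
    if config.run_repertoire and (d / "chains.airr.tsv").exists():
        chains, _ = io.read_airr(d / "chains.airr.tsv")
    return meta, assignments, markers, chains, None


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = io.config_hash(
        {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "outdir"  # the hash identifies the analysis, not its location
        }
    )
    report = RunReport(seed=config.seed, config_hash=cfg_hash)

    t0 = time.perf_counter()
    meta, assignments, markers, chains, truth = _load_inputs(config)
    validate_meta(meta)
    report.n_samples = int(len(meta))
    report.n_cells = int(len(assignments))
    report.timings_s["inputs"] = round(time.perf_counter() - t0, 3)
    if config.sim is not None:
        io.write_study(
            type("S", (), {"meta": meta, "assignments": assignments,
                           "markers": markers, "chains": chains})(),
            truth, out / "study", config.seed, cfg_hash,
        )

    # --- abundance ------------------------------------------------------
    t0 = time.perf_counter()
    assignments, dropped = filter_small_clusters(assignments, config.min_cells)
    report.dropped_clusters = dropped
    counts = counts_from_assignments(assignments, meta)
    props = compute_proportions(counts)
    io.write_tsv(
        counts.reset_index(), out / "cluster_counts.tsv", config.seed, cfg_hash
    )
    results = {}
    for name in CONTRASTS:
        if config.mode == "glmm":
            res = test_abundance_glmm(counts, meta, name)
        else:
            res = test_abundance_rank(props, meta, name)
        results[name] = res
        io.write_tsv(res, out / f"abundance_{name}.tsv", config.seed, cfg_hash)
    for direction in ("increase", "decrease"):
        calls = call_flare_associated(
            results["FlareV_vs_FlareB"], results["RemV_vs_RemB"],
            direction, config.alpha,
        )
        io.write_tsv(
            calls, out / f"flare_associated_{direction}.tsv", config.seed, cfg_hash
        )
        report.flare_associated[direction] = sorted(
            calls.loc[calls["associated"], "cluster_id"]
        )
    report.timings_s["abundance"] = round(time.perf_counter() - t0, 3)

    # --- expression -----------------------------------------------------
    if config.run_expression and markers is not None:
        t0 = time.perf_counter()
        de_frames = []
        for cluster in counts.columns:
            for name in CONTRASTS:
                try:
                    de_frames.append(
                        test_de(
                            markers, assignments, meta, cluster, name,
                            fc_threshold=config.fc_threshold,
                            pseudocount=config.pseudocount,
                            alpha=config.alpha,
                            min_expressing_fraction=config.min_expressing_fraction,
                        )
                    )
                except ValueError:
                    continue  # arm too small for this cluster/contrast
        de = (
            pd.concat(de_frames, ignore_index=True)
            if de_frames
            else pd.DataFrame()
        )
        io.write_tsv(de, out / "de_results.tsv", config.seed, cfg_hash)
        summary = count_de(de)
        io.write_tsv(summary, out / "de_counts.tsv", config.seed, cfg_hash)
        report.n_de_markers = {
            f"{r.cluster_id}:{r.contrast}": int(r.n_significant)
            for r in summary.itertuples()
            if r.n_significant
        }
        report.timings_s["expression"] = round(time.perf_counter() - t0, 3)

    # --- repertoire -----------------------------------------------------
    if config.run_repertoire and chains is not None:
        t0 = time.perf_counter()
        clonotypes, percell, log = call_clonotypes(chains, assignments, meta)
        report.excluded_cells = log
        io.write_tsv(clonotypes, out / "clonotypes.tsv", config.seed, cfg_hash)
        for compartment, sub in percell.groupby("compartment"):
            report.clonal_fractions[compartment] = clonal_fraction(
                int(sub["clonal"].sum()), len(sub)
            )
        div = diversity_table(percell)
        io.write_tsv(div, out / "diversity.tsv", config.seed, cfg_hash)
        io.write_tsv(
            hutcheson_comparisons(div), out / "diversity_tests.tsv",
            config.seed, cfg_hash,
        )
        for scope in ("whole", "subset"):
            shifts = clone_shift_tests(clonotypes, percell, scope)
            io.write_tsv(
                shifts, out / f"clone_shifts_{scope}.tsv", config.seed, cfg_hash
            )
            report.significant_clone_shifts[scope] = int(
                (shifts["p_adj"] < config.alpha).sum()
            ) if not shifts.empty else 0
        io.write_tsv(
            clone_cluster_distribution(percell),
            out / "clone_cluster_distribution.tsv", config.seed, cfg_hash,
        )
        report.timings_s["repertoire"] = round(time.perf_counter() - t0, 3)

    report.to_json(out / "report.json")
    return report
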