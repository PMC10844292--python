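"""Readers and writers for the pipeline's on-disk formats.

Tabular artifacts are TSV with a comment header (tool version, seed, config
hash) so every result file is self-describing; expression matrices are
MatrixMarket with feature/barcode sidecars; V(D)J chains follow the AIRR
Rearrangement column conventions; ground truth is JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .expression import MarkerMatrix

AIRR_COLUMNS = [
    "sequence_id", "cell_id", "locus", "productive", "junction",
    "junction_aa", "v_call", "j_call", "duplicate_count",
]
KNOWN_LOCI = {"TRA", "TRB", "TRG", "TRD", "IGH", "IGK", "IGL"}


def config_hash(obj) -> str:
    """Short stable digest of a configuration object."""
    text = json.dumps(obj, sort_keys=True, default=str) if not isinstance(obj, str) else obj
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, seed=None, cfg_hash=None, index=False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# flarekit v{__version__}")
        if seed is not None:
            fh.write(f" seed={seed}")
        if cfg_hash is not None:
            fh.write(f" config={cfg_hash}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_meta(path) -> pd.DataFrame:
    meta = read_tsv(path)
    for col in ("sample_id", "patient_id", "group", "visit"):
        if col not in meta.columns:
            raise ValueError(f"{path}: missing metadata column {col!r}")
    bad_group = set(meta["group"]) - {"flare", "dfr"}
    if bad_group:
        raise ValueError(f"{path}: unknown group values {sorted(bad_group)}")
    bad_visit = set(meta["visit"]) - {"baseline", "followup"}
    if bad_visit:
        raise ValueError(f"{path}: unknown visit values {sorted(bad_visit)}")
    return meta


def read_assignments(path) -> pd.DataFrame:
    df = read_tsv(path)
    for col in ("cell_id", "sample_id", "cluster_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing assignment column {col!r}")
    return df


def read_counts(path) -> pd.DataFrame:
    """Sample-by-cluster count table (first column = sample_id)."""
    df = read_tsv(path, index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{path}: cluster counts must be integers")
        df = df.round().astype(int)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    df.index.name = "sample_id"
    df.columns.name = "cluster_id"
    return df


def write_airr(chains: pd.DataFrame, path) -> None:
    out = chains.copy()
    out["productive"] = np.where(out["productive"].astype(bool), "T", "F")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)


def read_airr(path) -> tuple[pd.DataFrame, dict]:
    """AIRR Rearrangement TSV -> chain table restricted to productive rows.

    Returns (productive chains, log with rejected-row counts).
    """
    df = pd.read_csv(path, sep="\t", dtype={"junction": str, "junction_aa": str})
    for col in ("cell_id", "locus", "productive", "junction"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing AIRR column {col!r}")
    unknown = set(df["locus"]) - KNOWN_LOCI
    if unknown:
        raise ValueError(f"{path}: unknown locus values {sorted(unknown)}")
    prod = df["productive"].map(
        {"T": True, "F": False, True: True, False: False, "TRUE": True,
         "FALSE": False, "true": True, "false": False}
    )
    if prod.isna().any():
        raise ValueError(f"{path}: unparseable 'productive' values")
    df["productive"] = prod.astype(bool)
    malformed = df["junction"].isna() | (df["junction"] == "")
    log = {
        "rows": int(len(df)),
        "nonproductive": int((~df["productive"]).sum()),
        "malformed": int(malformed.sum()),
    }
    return df[~malformed], log


def write_markers(matrix: MarkerMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # MatrixMarket convention: features x cells, like cellranger exports
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(matrix.values.T))
    pd.DataFrame(
        {"feature_id": matrix.feature_ids, "feature_kind": matrix.feature_kind}
    ).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(matrix.cell_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_markers(outdir) -> MarkerMatrix:
    outdir = Path(outdir)
    try:
        mat = spio.mmread(outdir / "matrix.mtx")
    except ValueError as exc:
        raise ValueError(f"{outdir / 'matrix.mtx'}: malformed MatrixMarket ({exc})")
    features = pd.read_csv(outdir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    mat = sparse.csr_matrix(mat).T  # back to cells x features
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"{outdir}: matrix dims {mat.shape} do not match sidecars "
            f"({len(barcodes)} barcodes, {len(features)} features)"
        )
    return MarkerMatrix(
        values=mat,
        feature_ids=features[0].tolist(),
        feature_kind=features[1].to_numpy(dtype=object),
        cell_ids=barcodes,
    )


def write_ground_truth(truth, path) -> None:
    payload = {
        "true_flare_associated": {
            k: sorted(v) for k, v in truth.true_flare_associated.items()
        },
        "true_de": sorted(list(t) for t in truth.true_de),
        "true_expanded_clones": sorted(list(t) for t in truth.true_expanded_clones),
        "true_clonotypes": {
            f"{pid}::{key}": sorted(cells)
            for (pid, key), cells in sorted(truth.true_clonotypes.items())
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_study(study, truth, outdir, seed=None, cfg_hash=None) -> None:
    """Write a full simulated study in the pipeline's input schema."""
    outdir = Path(outdir)
    write_tsv(study.meta, outdir / "meta.tsv", seed, cfg_hash)
    write_tsv(study.assignments, outdir / "assignments.tsv", seed, cfg_hash)
    if study.markers is not None:
        write_markers(study.markers, outdir / "markers")
    if study.chains is not None:
        write_airr(study.chains, outdir / "chains.airr.tsv")
    if truth is not None:
        write_ground_truth(truth, outdir / "ground_truth.json")
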