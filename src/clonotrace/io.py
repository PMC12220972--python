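"""Readers and writers for the pipeline's on-disk formats.

Cell metadata and label tables are TSV; counts are MatrixMarket MTX
(cells x genes, 1-based indices) with genes.tsv / barcodes.tsv
sidecars; clonotype calls use an AIRR-rearrangement-style TSV dialect
(cell_id, locus, junction_aa, duplicate_count, score); ground truth is
JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import io as scio
from scipy import sparse

AIRR_COLUMNS = ["cell_id", "locus", "junction_aa", "duplicate_count", "score"]


def write_cells_tsv(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_cells_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str, "patient_id": str})


def write_airr_tsv(calls: pd.DataFrame, path) -> None:
    calls[AIRR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_airr_tsv(path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    missing = set(AIRR_COLUMNS) - set(calls.columns)
    if missing:
        raise ValueError(f"AIRR table {path} missing columns {sorted(missing)}")
    return calls


def write_counts_mtx(adata: ad.AnnData, outdir) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    scio.mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(X))
    genes = pd.DataFrame({
        "gene": adata.var_names,
        "is_mt": adata.var["is_mt"].to_numpy() if "is_mt" in adata.var
        else adata.var_names.str.startswith("MT-"),
    })
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame({"barcode": adata.obs_names}).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False
    )


def read_counts_mtx(indir) -> ad.AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(scio.mmread(str(indir / "matrix.mtx")))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", dtype={"barcode": str})
    var = pd.DataFrame(index=pd.Index(genes["gene"].astype(str), name="gene"))
    var["is_mt"] = genes["is_mt"].to_numpy() if "is_mt" in genes else \
        var.index.str.startswith("MT-")
    adata = ad.AnnData(X=X.astype(np.int32), var=var)
    adata.obs_names = barcodes["barcode"].astype(str)
    return adata


def write_dataset(outdir, cells: pd.DataFrame, adata: ad.AnnData, truth=None) -> None:
    """Write a simulated dataset (metadata, counts, optional truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cells_tsv(cells, outdir / "cells.tsv")
    write_counts_mtx(adata, outdir / "counts")
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")


def load_dataset(indir) -> tuple[pd.DataFrame, ad.AnnData]:
    indir = Path(indir)
    cells = read_cells_tsv(indir / "cells.tsv")
    adata = read_counts_mtx(indir / "counts")
    meta = cells.set_index("cell_id").reindex(adata.obs_names)
    for col in meta.columns:
        adata.obs[col] = meta[col].to_numpy()
    return cells, adata
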