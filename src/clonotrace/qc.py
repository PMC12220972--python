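"""Cell-level QC, normalization, signature scoring and positivity calls.

Cells with a mitochondrial count fraction strictly greater than 10% are
removed; surviving cells are scaled to a fixed total (10,000 counts by
default) and log2(1 + x) transformed.  Signature scores are the mean
normalized expression of the signature genes minus that of a
size-matched random background set drawn with a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse


@dataclass(frozen=True)
class QCThresholds:
    mito_max_fraction: float = 0.10
    target_sum: float = 10_000.0

    def __post_init__(self):
        if not (0.0 < self.mito_max_fraction < 1.0):
            raise ValueError("mito_max_fraction must be in (0, 1)")
        if self.target_sum <= 0:
            raise ValueError("target_sum must be > 0")


def _counts(adata: ad.AnnData) -> sparse.csr_matrix:
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    return sparse.csr_matrix(X)


def mito_fraction(adata: ad.AnnData) -> np.ndarray:
    """Per-cell fraction of counts in mitochondrial genes (NaN if total 0)."""
    if "is_mt" not in adata.var:
        adata.var["is_mt"] = adata.var_names.str.startswith("MT-")
    if not adata.var["is_mt"].any():
        raise ValueError("no mitochondrial genes flagged (var['is_mt'])")
    X = _counts(adata)
    total = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(X[:, adata.var["is_mt"].to_numpy()].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), np.nan)
    return frac


def filter_cells(adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()
                 ) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove cells with mito fraction strictly above the threshold.

    Cells with zero total counts have an undefined mito fraction and are
    removed with reason ``zero_counts``.  Returns the filtered AnnData
    (a copy) and a report listing removed cells with their fraction.
    """
    frac = mito_fraction(adata)
    zero = np.isnan(frac)
    high = ~zero & (frac > thresholds.mito_max_fraction)
    removed = zero | high
    report = pd.DataFrame({
        "cell_id": adata.obs_names[removed],
        "mito_fraction": frac[removed],
        "reason": np.where(zero[removed], "zero_counts", "high_mito"),
    })
    out = adata[~removed].copy()
    out.obs["mito_fraction"] = frac[~removed]
    return out, report


def normalize_log(adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()
                  ) -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts, then log2(1 + x).

    Raw counts are preserved in ``layers['counts']``.  Cells with zero
    total counts must be filtered first (error otherwise).
    """
    X = _counts(adata)
    total = np.asarray(X.sum(axis=1)).ravel()
    if (total == 0).any():
        raise ValueError("zero-total cells present; run filter_cells first")
    scale = thresholds.target_sum / total
    norm = sparse.diags(scale) @ X.astype(float)
    norm.data = np.log2(1.0 + norm.data)
    out = adata.copy()
    out.layers["counts"] = X
    out.X = norm.tocsr()
    return out


def signature_score(adata: ad.AnnData, genes, seed: int = 0,
                    background_size: int | None = None) -> np.ndarray:
    """Background-corrected per-cell signature score.

    Mean normalized expression over the signature genes minus the mean
    over a size-matched random background drawn (with ``seed``) from
    genes outside the signature.  Signature genes missing from the
    matrix are dropped with a warning; an empty intersection is an
    error.
    """
    present = [g for g in genes if g in adata.var_names]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}")
    if not present:
        raise ValueError("no signature genes present in the matrix")
    pool = adata.var_names[~adata.var_names.isin(present)]
    size = background_size or len(present)
    if size > len(pool):
        raise ValueError("background pool smaller than requested background size")
    rng = np.random.default_rng(seed)
    background = pool[rng.choice(len(pool), size=size, replace=False)]
    X = sparse.csr_matrix(adata.X)
    sig = np.asarray(X[:, adata.var_names.isin(present)].mean(axis=1)).ravel()
    bg = np.asarray(X[:, adata.var_names.isin(background)].mean(axis=1)).ravel()
    return sig - bg


def transcript_positive(adata: ad.AnnData, gene: str, min_count: int = 1) -> np.ndarray:
    """Boolean per-cell call: raw count of ``gene`` >= ``min_count``."""
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not in matrix")
    col = adata.var_names.get_loc(gene)
    X = _counts(adata)
    return np.asarray(X[:, col].todense()).ravel() >= min_count
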