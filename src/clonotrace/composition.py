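"""Phenotype and transcript-state composition of clusters and categories.

Category tables (all / expanded / matched) are computed over cells;
cluster-level tables (pre/post tracking, KLRG1/MKI67 transcript states)
weight each cluster equally, mirroring how per-cluster percentages are
summarized in longitudinal repertoire studies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .simulate import PHENOTYPES
from .qc import transcript_positive

CATEGORIES = ("all", "expanded", "matched")

STATE_LABELS = ("K+M-", "K-M+", "K+M+", "K-M-")


def _proportions(sub: pd.DataFrame, phenotypes) -> dict:
    n = len(sub)
    counts = sub["phenotype"].value_counts()
    row = {p: (counts.get(p, 0) / n if n else 0.0) for p in phenotypes}
    row["n_cells"] = n
    row["empty"] = n == 0
    return row


def composition_by_category(labels: pd.DataFrame,
                            by=("patient_id", "compartment", "lineage"),
                            phenotypes=PHENOTYPES) -> pd.DataFrame:
    """Phenotype proportions per stratum for all/expanded/matched cells.

    ``labels`` must carry phenotype, expanded and matched columns (from
    the network stage).  Zero-cell strata are emitted flagged empty so
    every stratum x category combination is present.
    """
    required = {"phenotype", "expanded", "matched", *by}
    missing = required - set(labels.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    if labels["phenotype"].isna().any():
        raise ValueError("unlabeled cells (NaN phenotype) in label table")
    rows = []
    for keys, grp in labels.groupby(list(by), observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for category in CATEGORIES:
            if category == "all":
                sub = grp
            elif category == "expanded":
                sub = grp[grp["expanded"]]
            else:
                sub = grp[grp["matched"]]
            row = dict(zip(by, keys))
            row["category"] = category
            row.update(_proportions(sub, phenotypes))
            rows.append(row)
    return pd.DataFrame(rows)


def cluster_phenotype_fraction(labels: pd.DataFrame, phenotype: str,
                               compartment: str = "blood",
                               matched_only: bool = True,
                               min_cells: int = 1) -> pd.DataFrame:
    """Per-cluster fraction of one phenotype, by timepoint.

    Restricted to one compartment (the longitudinal one, blood by
    default) and, by default, to blood-tumor matched clusters.  Returns
    one row per patient x lineage x cluster x timepoint with the
    fraction and cell count; clusters need >= min_cells at a timepoint
    to contribute that row.
    """
    df = labels[labels["compartment"] == compartment]
    if matched_only:
        df = df[df["matched"]]
    if df.empty:
        return pd.DataFrame(columns=["patient_id", "lineage", "cluster_id",
                                     "timepoint", "fraction", "n_cells"])
    out = (
        df.assign(is_target=df["phenotype"] == phenotype)
        .groupby(["patient_id", "lineage", "cluster_id", "timepoint"], observed=True)
        .agg(fraction=("is_target", "mean"), n_cells=("is_target", "size"))
        .reset_index()
    )
    return out[out["n_cells"] >= min_cells].reset_index(drop=True)


def cluster_state_fractions(labels: pd.DataFrame, adata,
                            genes=("KLRG1", "MKI67"),
                            compartment: str = "blood",
                            timepoints=("pre", "post"),
                            matched_only: bool = True,
                            min_cells: int = 3) -> pd.DataFrame:
    """Joint transcript-state fractions per cluster and timepoint.

    For gene pair (K, M) each cell is assigned one of the four states
    K+M-, K-M+, K+M+, K-M- by raw-count positivity; fractions are
    reported per cluster per timepoint.  Only clusters observed with at
    least ``min_cells`` cells at every requested timepoint are kept;
    others are excluded with a warning.
    """
    gk, gm = genes
    pos_k = pd.Series(transcript_positive(adata, gk), index=adata.obs_names)
    pos_m = pd.Series(transcript_positive(adata, gm), index=adata.obs_names)

    df = labels[(labels["compartment"] == compartment)
                & (labels["timepoint"].isin(timepoints))].copy()
    if matched_only:
        df = df[df["matched"]]
    df = df[df["cell_id"].isin(pos_k.index)]
    df["k"] = pos_k.loc[df["cell_id"]].to_numpy()
    df["m"] = pos_m.loc[df["cell_id"]].to_numpy()
    df["state"] = np.select(
        [df["k"] & ~df["m"], ~df["k"] & df["m"], df["k"] & df["m"]],
        ["K+M-", "K-M+", "K+M+"], default="K-M-",
    )

    key = ["patient_id", "lineage", "cluster_id"]
    counts = df.groupby(key + ["timepoint"], observed=True).size().unstack("timepoint")
    counts = counts.reindex(columns=list(timepoints))
    ok = (counts.fillna(0) >= min_cells).all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(
            f"{dropped} clusters excluded: fewer than {min_cells} cells "
            f"at one or more of {tuple(timepoints)}"
        )
    keep = counts.index[ok]
    df = df.set_index(key).loc[df.set_index(key).index.isin(keep)].reset_index()

    rows = []
    for (pat, lin, cl, tp), grp in df.groupby(key + ["timepoint"], observed=True):
        n = len(grp)
        frac = grp["state"].value_counts()
        row = {"patient_id": pat, "lineage": lin, "cluster_id": cl,
               "timepoint": tp, "n_cells": n}
        for s in STATE_LABELS:
            row[s] = frac.get(s, 0) / n
        rows.append(row)
    return pd.DataFrame(rows)


def timepoint_shift(percluster: pd.DataFrame, value_col: str = "fraction",
                    pre: str = "pre", post: str = "post") -> tuple[pd.DataFrame, dict]:
    """Paired pre/post values per cluster and the mean shift.

    ``percluster`` is long format with patient_id, lineage, cluster_id,
    timepoint and a value column.  Clusters present at both timepoints
    form the paired table (value_post - value_pre); at least one paired
    cluster is required.
    """
    key = ["patient_id", "lineage", "cluster_id"]
    wide = percluster.pivot_table(index=key, columns="timepoint",
                                  values=value_col, aggfunc="first")
    for tp in (pre, post):
        if tp not in wide.columns:
            wide[tp] = np.nan
    paired = wide.dropna(subset=[pre, post]).reset_index()
    if len(paired) < 1:
        raise ValueError("no clusters observed at both timepoints")
    paired = paired[key + [pre, post]].copy()
    paired["shift"] = paired[post] - paired[pre]
    summary = {
        "n_clusters": int(len(paired)),
        "mean_pre": float(paired[pre].mean()),
        "mean_post": float(paired[post].mean()),
        "mean_shift": float(paired["shift"].mean()),
    }
    return paired, summary


def mean_cluster_composition(labels: pd.DataFrame,
                             by=("lineage", "compartment", "timepoint"),
                             phenotypes=PHENOTYPES) -> pd.DataFrame:
    """Mean per-cluster phenotype composition per condition (radar-style).

    Each cluster's phenotype proportions are computed first, then
    averaged with equal cluster weight within each condition.
    """
    key = ["patient_id", "lineage", "cluster_id"] + [c for c in by if c not in
                                                     ("patient_id", "lineage")]
    rows = []
    for keys, grp in labels.groupby(key, observed=True):
        row = dict(zip(key, keys))
        row.update(_proportions(grp, phenotypes))
        rows.append(row)
    per_cluster = pd.DataFrame(rows)
    return (
        per_cluster.groupby(list(by), observed=True)[list(phenotypes)]
        .mean()
        .reset_index()
    )
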