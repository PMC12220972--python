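"""Per-patient, per-lineage TCR identity networks and clonal clusters.

Two cells are connected iff the Levenshtein distance between their
alpha-chain CDR3s is 0 AND between their beta-chain CDR3s is 0 - i.e.
both junctions are identical.  Because distance 0 is string identity,
connected components can be computed by exact-match grouping on the
(cdr3a, cdr3b) pair; the test suite proves this equivalent to the
brute-force pairwise-distance construction.  Clusters (connected
components, singletons included) carry stable integer ids ordered by
their smallest member cell id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
import networkx as nx


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitutions, insertions, deletions)."""
    if a == b:
        return 0
    return int(edlib.align(a, b, task="distance")["editDistance"])


@dataclass
class NetworkMetrics:
    """Cluster-count and max-cluster-size summaries of one network.

    Normalized values divide by the number of cells and take log10, so
    both are <= 0; a fully unique repertoire has n_clusters_norm = 0.
    """

    n_cells: int
    n_clusters: int
    max_cluster_size: int
    n_clusters_norm: float
    max_size_norm: float


@dataclass
class ClonalNetwork:
    """One patient x lineage identity network.

    ``cells`` has one row per cell: cell_id, cdr3a, cdr3b, compartment,
    timepoint, phenotype, cluster_id, cluster_size, degree; after
    labeling also expanded and matched.
    """

    patient_id: str
    lineage: str
    cells: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_clusters(self) -> int:
        return int(self.cells["cluster_id"].nunique())

    def to_graph(self) -> nx.Graph:
        """Explicit graph with clique edges inside each cluster."""
        g = nx.Graph()
        for row in self.cells.itertuples():
            g.add_node(row.cell_id, cluster_id=int(row.cluster_id),
                       compartment=row.compartment, phenotype=row.phenotype)
        for _, grp in self.cells.groupby("cluster_id"):
            ids = grp["cell_id"].tolist()
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    g.add_edge(ids[i], ids[j])
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)


METADATA_COLUMNS = ("patient_id", "compartment", "timepoint", "lineage", "phenotype")


def _assign_clusters(df: pd.DataFrame) -> pd.DataFrame:
    """Cluster by exact (cdr3a, cdr3b) identity; canonical integer ids."""
    df = df.sort_values("cell_id", kind="mergesort").reset_index(drop=True)
    key = df["cdr3a"] + "\x00" + df["cdr3b"]
    first_pos = {}
    order = []
    for k in key:
        if k not in first_pos:
            first_pos[k] = len(first_pos)
        order.append(first_pos[k])
    df["cluster_id"] = order  # ordered by smallest member cell_id
    sizes = df.groupby("cluster_id")["cell_id"].transform("size")
    df["cluster_size"] = sizes.astype(int)
    df["degree"] = df["cluster_size"] - 1
    return df


def build_networks(pairs: pd.DataFrame, cells: pd.DataFrame
                   ) -> dict[tuple[str, str], ClonalNetwork]:
    """Build one identity network per patient x lineage.

    ``pairs``: cell_id, cdr3a, cdr3b.  ``cells``: metadata with at least
    cell_id plus METADATA_COLUMNS.  Every paired cell must have
    metadata; offending ids raise a ValueError.
    """
    meta = cells.set_index("cell_id")
    unknown = pairs.loc[~pairs["cell_id"].isin(meta.index), "cell_id"]
    if len(unknown):
        raise ValueError(
            f"{len(unknown)} paired cells lack metadata, e.g. {unknown.head(5).tolist()}"
        )
    merged = pairs.merge(cells[["cell_id", *METADATA_COLUMNS]], on="cell_id", how="left")
    networks = {}
    for (patient, lineage), grp in merged.groupby(["patient_id", "lineage"], observed=True, sort=True):
        networks[(patient, lineage)] = ClonalNetwork(
            patient_id=str(patient), lineage=str(lineage),
            cells=_assign_clusters(grp.drop(columns=["patient_id", "lineage"])).assign(
                patient_id=patient, lineage=lineage
            ),
        )
    return networks


def label_cells(network: ClonalNetwork) -> pd.DataFrame:
    """Label each cell expanded/unique and blood-tumor matched/nonmatched.

    Expanded: node degree > 0 (cluster size > 1).  Matched: the cell's
    cluster contains at least one blood cell and at least one tumor
    cell.  NAT cells are carried in the network but never confer
    matched status.
    """
    df = network.cells.copy()
    df["expanded"] = df["degree"] > 0
    presence = (
        df.assign(_blood=df["compartment"] == "blood",
                  _tumor=df["compartment"] == "tumor")
        .groupby("cluster_id")[["_blood", "_tumor"]].any()
    )
    matched_clusters = presence["_blood"] & presence["_tumor"]
    df["matched"] = df["cluster_id"].map(matched_clusters).astype(bool)
    network.cells = df
    return df


def concat_labels(networks: dict[tuple[str, str], ClonalNetwork],
                  label: bool = True) -> pd.DataFrame:
    """Single per-cell label table across all networks."""
    frames = []
    for net in networks.values():
        if label and "matched" not in net.cells.columns:
            label_cells(net)
        frames.append(net.cells)
    return pd.concat(frames, ignore_index=True)


def network_metrics(cells: pd.DataFrame | ClonalNetwork) -> NetworkMetrics | None:
    """Metrics for a network or any cell subset of one (None if empty).

    For subsets (e.g. matched-only cells) clusters are recomputed from
    the subset's clonotypes, which equals restricting the identity
    graph to those nodes.
    """
    if isinstance(cells, ClonalNetwork):
        cells = cells.cells
    n = len(cells)
    if n == 0:
        return None
    sizes = cells.groupby(["cdr3a", "cdr3b"]).size()
    n_clusters = int(len(sizes))
    max_size = int(sizes.max())
    return NetworkMetrics(
        n_cells=n,
        n_clusters=n_clusters,
        max_cluster_size=max_size,
        n_clusters_norm=math.log10(n_clusters / n),
        max_size_norm=math.log10(max_size / n),
    )


def metrics_table(networks: dict[tuple[str, str], ClonalNetwork],
                  split_by_compartment: bool = True) -> pd.DataFrame:
    """Long table of network metrics per patient x lineage (x specimen)."""
    rows = []
    for (patient, lineage), net in networks.items():
        subsets = (
            net.cells.groupby("compartment", observed=True)
            if split_by_compartment else [("all", net.cells)]
        )
        for compartment, sub in subsets:
            m = network_metrics(sub)
            if m is None:
                continue
            rows.append({
                "patient_id": patient, "lineage": lineage, "compartment": compartment,
                "n_cells": m.n_cells, "n_clusters": m.n_clusters,
                "max_cluster_size": m.max_cluster_size,
                "n_clusters_norm": m.n_clusters_norm, "max_size_norm": m.max_size_norm,
            })
    return pd.DataFrame(rows)


def cluster_phenotype_cluster_counts(networks: dict[tuple[str, str], ClonalNetwork]
                                     ) -> pd.DataFrame:
    """Number of clusters containing each phenotype, by matched status.

    One row per patient x lineage x matched-status x phenotype with the
    count of clusters in which that phenotype occurs, and the number of
    cells in the stratum (for normalization).
    """
    rows = []
    for (patient, lineage), net in networks.items():
        df = net.cells
        if "matched" not in df.columns:
            df = label_cells(net)
        for matched, sub in df.groupby("matched"):
            n_cells = len(sub)
            counts = sub.groupby("phenotype", observed=False)["cluster_id"].nunique()
            for phen, k in counts.items():
                rows.append({
                    "patient_id": patient, "lineage": lineage,
                    "matched": bool(matched), "phenotype": phen,
                    "n_clusters": int(k), "n_cells": int(n_cells),
                })
    return pd.DataFrame(rows)
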