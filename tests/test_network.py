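"""Identity networks: distances, components, labels, metrics."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonotrace import (
    levenshtein, build_networks, label_cells, concat_labels, network_metrics,
    cluster_phenotype_cluster_counts,
)


def dp_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming edit-distance oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_force_components(pairs: pd.DataFrame) -> list[frozenset]:
    """O(n^2) pairwise-distance clustering: edge iff both chains at distance 0."""
    g = nx.Graph()
    g.add_nodes_from(pairs["cell_id"])
    rec = pairs.to_dict(orient="records")
    for i in range(len(rec)):
        for j in range(i + 1, len(rec)):
            if (levenshtein(rec[i]["cdr3a"], rec[j]["cdr3a"]) == 0
                    and levenshtein(rec[i]["cdr3b"], rec[j]["cdr3b"]) == 0):
                g.add_edge(rec[i]["cell_id"], rec[j]["cell_id"])
    return sorted(
        (frozenset(c) for c in nx.connected_components(g)), key=lambda c: min(c)
    )


@pytest.mark.parametrize("a,b,d", [
    ("CASSLGQAYEQYF", "CASSLGQAYEQYF", 0),
    ("", "CASS", 4),
    ("kitten", "sitting", 3),
])
def test_levenshtein_known_values(a, b, d):
    assert levenshtein(a, b) == d
    assert dp_levenshtein(a, b) == d


aa = st.text(alphabet="ACDEFGHIK", min_size=0, max_size=10)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(a=aa, b=aa, c=aa)
def test_levenshtein_metric_axioms_against_dp_oracle(a, b, c):
    d_ab = levenshtein(a, b)
    assert d_ab == dp_levenshtein(a, b)
    assert d_ab == levenshtein(b, a)
    assert (d_ab == 0) == (a == b)
    assert d_ab <= levenshtein(a, c) + levenshtein(c, b)


def _cells(rows):
    return pd.DataFrame(rows, columns=["cell_id", "patient_id", "compartment",
                                       "timepoint", "lineage", "phenotype"])


def _pairs(rows):
    return pd.DataFrame(rows, columns=["cell_id", "cdr3a", "cdr3b"])


@pytest.fixture
def six_cell_example():
    """Three identical clonotypes across compartments, a near-miss pair, a singleton."""
    pairs = _pairs([
        ("c1", "CAVRDF", "CASSLGF"), ("c2", "CAVRDF", "CASSLGF"),
        ("c3", "CAVRDF", "CASSLGF"),
        ("c4", "CAAAAF", "CASSQYF"), ("c5", "CAAAAF", "CASSQFF"),  # beta differs by 1
        ("c6", "CAWWWF", "CASSWWF"),
    ])
    cells = _cells([
        ("c1", "P1", "blood", "pre", "CD4", "GZMB+"),
        ("c2", "P1", "blood", "post", "CD4", "Prolif"),
        ("c3", "P1", "tumor", "post", "CD4", "GZMK+"),
        ("c4", "P1", "blood", "pre", "CD4", "Naive"),
        ("c5", "P1", "blood", "pre", "CD4", "Naive"),
        ("c6", "P1", "tumor", "post", "CD4", "Treg"),
    ])
    return pairs, cells


def test_components_match_bruteforce_on_example(six_cell_example):
    pairs, cells = six_cell_example
    nets = build_networks(pairs, cells)
    net = nets[("P1", "CD4")]
    observed = sorted(
        (frozenset(g["cell_id"]) for _, g in net.cells.groupby("cluster_id")),
        key=lambda c: min(c),
    )
    assert observed == brute_force_components(pairs)
    assert observed[0] == frozenset({"c1", "c2", "c3"})


def test_shared_alpha_alone_does_not_connect(six_cell_example):
    pairs, cells = six_cell_example
    net = build_networks(pairs, cells)[("P1", "CD4")]
    cl = net.cells.set_index("cell_id")["cluster_id"]
    assert cl["c4"] != cl["c5"]


def test_matched_and_expanded_labels(six_cell_example):
    pairs, cells = six_cell_example
    net = build_networks(pairs, cells)[("P1", "CD4")]
    labels = label_cells(net).set_index("cell_id")
    assert labels.loc[["c1", "c2", "c3"], "matched"].all()
    assert labels.loc[["c1", "c2", "c3"], "expanded"].all()
    assert not labels.loc[["c4", "c5", "c6"], "matched"].any()
    assert not labels.loc[["c4", "c5", "c6"], "expanded"].any()


def test_single_cell_is_singleton_cluster():
    net = build_networks(
        _pairs([("c1", "CAVF", "CASSF")]),
        _cells([("c1", "P1", "blood", "pre", "CD4", "Naive")]),
    )[("P1", "CD4")]
    assert net.n_clusters == 1
    assert net.cells["cluster_size"].iloc[0] == 1


def test_missing_metadata_is_hard_error(six_cell_example):
    pairs, cells = six_cell_example
    with pytest.raises(ValueError, match="lack metadata"):
        build_networks(pairs, cells.iloc[:-1])


def test_nat_cells_never_confer_matched_status():
    pairs = _pairs([("c1", "CAVF", "CASSF"), ("c2", "CAVF", "CASSF")])
    cells = _cells([
        ("c1", "P1", "blood", "pre", "CD4", "Naive"),
        ("c2", "P1", "NAT", "post", "CD4", "Naive"),
    ])
    net = build_networks(pairs, cells)[("P1", "CD4")]
    labels = label_cells(net)
    assert labels["expanded"].all()
    assert not labels["matched"].any()


def test_matched_labeling_is_monotone_in_tumor_cells():
    """Adding a tumor cell to a blood cluster can only create matches."""
    pairs = _pairs([("c1", "CAVF", "CASSF"), ("c2", "CAVF", "CASSF")])
    cells = _cells([
        ("c1", "P1", "blood", "pre", "CD4", "Naive"),
        ("c2", "P1", "blood", "pre", "CD4", "Naive"),
    ])
    before = label_cells(build_networks(pairs, cells)[("P1", "CD4")])
    pairs2 = pd.concat([pairs, _pairs([("c9", "CAVF", "CASSF")])], ignore_index=True)
    cells2 = pd.concat(
        [cells, _cells([("c9", "P1", "tumor", "post", "CD4", "GZMB+")])],
        ignore_index=True,
    )
    after = label_cells(build_networks(pairs2, cells2)[("P1", "CD4")])
    merged = before.merge(after, on="cell_id", suffixes=("_before", "_after"))
    assert (merged["matched_before"] <= merged["matched_after"]).all()


def test_groups_split_by_patient_and_lineage():
    pairs = _pairs([("c1", "CAVF", "CASSF"), ("c2", "CAVF", "CASSF"),
                    ("c3", "CAVF", "CASSF")])
    cells = _cells([
        ("c1", "P1", "blood", "pre", "CD4", "Naive"),
        ("c2", "P1", "tumor", "post", "CD8", "GZMB+"),
        ("c3", "P2", "tumor", "post", "CD4", "GZMB+"),
    ])
    nets = build_networks(pairs, cells)
    assert set(nets) == {("P1", "CD4"), ("P1", "CD8"), ("P2", "CD4")}
    # identical clonotype never links across patients or lineages
    for net in nets.values():
        assert not label_cells(net)["matched"].any()


def test_cluster_ids_stable_under_input_permutation(six_cell_example):
    pairs, cells = six_cell_example
    a = build_networks(pairs, cells)[("P1", "CD4")].cells
    shuffled = pairs.sample(frac=1.0, random_state=3).reset_index(drop=True)
    b = build_networks(shuffled, cells)[("P1", "CD4")].cells
    merged = a.merge(b, on="cell_id", suffixes=("_a", "_b"))
    assert (merged["cluster_id_a"] == merged["cluster_id_b"]).all()


def test_cluster_sizes_sum_to_cells(labeled):
    for net in labeled.networks.values():
        sizes = net.cells.groupby("cluster_id")["cluster_size"].first()
        assert sizes.sum() == net.n_cells


def _clusters_df(sizes):
    rows = []
    for k, size in enumerate(sizes):
        rows += [(f"c{k}_{i}", f"CA{k}F", f"CASS{k}F") for i in range(size)]
    return pd.DataFrame(rows, columns=["cell_id", "cdr3a", "cdr3b"])


@pytest.mark.parametrize("sizes,expected_nc,expected_ms", [
    ([10] * 10, -1.0, -1.0),            # 100 cells, 10 clusters
    ([5] + [1] * 95, None, math.log10(0.05)),  # max cluster 5 of 100
    ([1] * 40, 0.0, math.log10(1 / 40)),       # fully unique repertoire
])
def test_network_metrics_forced_arithmetic(sizes, expected_nc, expected_ms):
    m = network_metrics(_clusters_df(sizes))
    assert m.n_cells == sum(sizes)
    if expected_nc is not None:
        assert m.n_clusters_norm == pytest.approx(expected_nc)
    assert m.max_size_norm == pytest.approx(expected_ms, abs=1e-4)
    assert m.n_clusters_norm <= 0 and m.max_size_norm <= 0


def test_network_metrics_empty_subset_is_null():
    assert network_metrics(pd.DataFrame(columns=["cell_id", "cdr3a", "cdr3b"])) is None


def test_hash_clustering_equals_bruteforce_on_random_instances():
    """Exact-match grouping reproduces pairwise Levenshtein-0 components."""
    rng = np.random.default_rng(11)
    from clonotrace.simulate import _batch_cdr3

    for _ in range(15):
        n = int(rng.integers(10, 120))
        n_clones = max(2, n // 3)
        alphas = _batch_cdr3(rng, n_clones, "CA", "F")
        betas = _batch_cdr3(rng, n_clones, "CASS", "F")
        ix = rng.integers(0, n_clones, size=n)
        pairs = _pairs([(f"c{i:03d}", alphas[k], betas[k]) for i, k in enumerate(ix)])
        # sprinkle distance-1 near misses that must NOT join
        near = pairs.iloc[0]
        pairs.loc[len(pairs)] = ("c_near", near["cdr3a"], near["cdr3b"][:-2] + "YF")
        cells = _cells([(cid, "P1", "blood", "pre", "CD4", "Naive")
                        for cid in pairs["cell_id"]])
        net = build_networks(pairs, cells)[("P1", "CD4")]
        observed = sorted(
            (frozenset(g["cell_id"]) for _, g in net.cells.groupby("cluster_id")),
            key=lambda c: min(c),
        )
        assert observed == brute_force_components(pairs)


def test_phenotype_cluster_counts(six_cell_example):
    pairs, cells = six_cell_example
    nets = build_networks(pairs, cells)
    label_cells(nets[("P1", "CD4")])
    counts = cluster_phenotype_cluster_counts(nets)
    matched = counts[counts["matched"]]
    assert set(matched["phenotype"]) == {"GZMB+", "Prolif", "GZMK+"}
    assert (matched["n_clusters"] == 1).all()
    naive = counts[(~counts["matched"]) & (counts["phenotype"] == "Naive")]
    assert naive["n_clusters"].iloc[0] == 2


def test_graphml_export(tmp_path, six_cell_example):
    pairs, cells = six_cell_example
    net = build_networks(pairs, cells)[("P1", "CD4")]
    path = tmp_path / "net.graphml"
    net.write_graphml(path)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == 6
    assert g.number_of_edges() == 3  # triangle c1-c2-c3
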