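"""Heterogeneous-graph path index, enrichment tests, rewiring null and
diffusion scoring."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from climbmet import keggnet as kn
from climbmet import synthetic as syn


def _graph_from_edges(edges, classes):
    g = nx.Graph()
    for n, k in classes.items():
        g.add_node(n, klass=k)
    g.add_edges_from(edges)
    return kn.HeteroGraph(g)


def test_load_graph_toy(tmp_path):
    pd.DataFrame({"node_id": ["m1", "r1", "m2"],
                  "class": ["metabolite", "reaction", "metabolite"]}
                 ).to_csv(tmp_path / "n.tsv", sep="\t", index=False)
    pd.DataFrame({"node_a": ["m1", "r1"], "node_b": ["r1", "m2"]}
                 ).to_csv(tmp_path / "e.tsv", sep="\t", index=False)
    g = kn.load_graph(tmp_path / "n.tsv", tmp_path / "e.tsv")
    assert g.g.number_of_nodes() == 3 and g.g.number_of_edges() == 2


def test_load_graph_rejects_metabolite_edge(tmp_path):
    pd.DataFrame({"node_id": ["m1", "m2"], "class": ["metabolite"] * 2}
                 ).to_csv(tmp_path / "n.tsv", sep="\t", index=False)
    pd.DataFrame({"node_a": ["m1"], "node_b": ["m2"]}
                 ).to_csv(tmp_path / "e.tsv", sep="\t", index=False)
    with pytest.raises(ValueError, match="metabolite-metabolite"):
        kn.load_graph(tmp_path / "n.tsv", tmp_path / "e.tsv")


def test_load_graph_rejects_dangling_edge(tmp_path):
    pd.DataFrame({"node_id": ["m1"], "class": ["metabolite"]}
                 ).to_csv(tmp_path / "n.tsv", sep="\t", index=False)
    pd.DataFrame({"node_a": ["m1"], "node_b": ["ghost"]}
                 ).to_csv(tmp_path / "e.tsv", sep="\t", index=False)
    with pytest.raises(ValueError, match="missing"):
        kn.load_graph(tmp_path / "n.tsv", tmp_path / "e.tsv")


def test_path_index_chain_and_diamond():
    chain = _graph_from_edges(
        [("m1", "r1"), ("r1", "m2")],
        {"m1": "metabolite", "m2": "metabolite", "r1": "reaction"})
    idx = kn.build_path_index(chain)
    assert idx.pair_distance("m1", "m2") == 2
    assert idx.pair_length("m1", "m2") == 1
    assert idx.pair_path_count("m1", "m2") == 1
    assert idx.pair_nodes("m1", "m2") == {"r1"}

    diamond = _graph_from_edges(
        [("m1", "r1"), ("r1", "m2"), ("m1", "r2"), ("r2", "m2")],
        {"m1": "metabolite", "m2": "metabolite", "r1": "reaction",
         "r2": "reaction"})
    idx2 = kn.build_path_index(diamond)
    assert idx2.pair_path_count("m1", "m2") == 2
    assert idx2.pair_nodes("m1", "m2") == {"r1", "r2"}


def _brute_force_pair(g, s, t):
    try:
        paths = list(nx.all_shortest_paths(g, s, t))
    except nx.NetworkXNoPath:
        return None
    nodes = set().union(*[set(p) for p in paths]) - {s, t}
    return len(paths[0]) - 1, len(paths), nodes


def test_path_index_matches_enumeration_on_random_graphs(default_graph,
                                                         default_path_index):
    g, idx = default_graph, default_path_index
    rng = np.random.default_rng(0)
    mets = g.metabolites
    for _ in range(40):
        s, t = rng.choice(len(mets), 2, replace=False)
        s, t = mets[s], mets[t]
        oracle = _brute_force_pair(g.g, s, t)
        if oracle is None:
            assert not np.isfinite(idx.pair_distance(s, t))
            continue
        d, count, nodes = oracle
        assert idx.pair_distance(s, t) == d
        assert idx.pair_path_count(s, t) == count
        assert idx.pair_nodes(s, t) == nodes


def test_path_length_enrichment_identical_is_zero(default_path_index):
    idx = default_path_index
    out = kn.path_length_enrichment(idx, idx.pairs)
    assert out["chi2"] == pytest.approx(0.0, abs=1e-9)
    assert out["p"] == pytest.approx(1.0)


def test_path_length_enrichment_detects_proximity(default_path_index):
    idx = default_path_index
    close = [p for p in idx.pairs if idx.pair_length(*p) == 1][:25]
    out = kn.path_length_enrichment(idx, close)
    assert out["p"] < 0.01


def test_node_enrichment_pair_fraction_arithmetic():
    # the headline counts: 5 of 29 pairs vs 46 of 8778
    assert 100 * 5 / 29 == pytest.approx(17.2, abs=0.05)
    assert 100 * 46 / 8778 == pytest.approx(0.52, abs=0.005)


def _hypergeom_tail_oracle(a, N, A, n):
    """P(X >= a) by exhaustive summation of the hypergeometric pmf."""
    from math import comb

    total = 0
    for x in range(a, min(A, n) + 1):
        total += comb(A, x) * comb(N - A, n - x)
    return total / comb(N, n)


def test_hypergeometric_matches_exhaustive_tail():
    p_scipy = float(stats.hypergeom.sf(5 - 1, 8778, 46, 29))
    p_oracle = _hypergeom_tail_oracle(5, 8778, 46, 29)
    assert abs(p_scipy - p_oracle) < 1e-12


def test_node_enrichment_trivial_and_planted(default_path_index):
    idx = default_path_index
    pairs = idx.pairs
    counts = idx.node_pair_counts(pairs)
    # node on every selected pair, when it is on every background pair of a
    # sub-universe: p must be 1 for a node contained in all pairs
    focal = max(counts, key=counts.get)
    through = [p for p in pairs if idx.node_on_path(focal, *p)]
    out = kn.node_enrichment(idx, through[:10])
    row = out[out["node"] == focal].iloc[0]
    assert row["a"] == 10
    # planted: rare node over-represented in the selection ranks first by q
    rare = [v for v, c in sorted(counts.items(), key=lambda kv: kv[1])
            if 15 <= c <= 40][0]
    rare_through = [p for p in pairs if idx.node_on_path(rare, *p)][:5]
    rng = np.random.default_rng(1)
    others = [p for p in pairs if not idx.node_on_path(rare, *p)]
    sel = rare_through + [others[i] for i in rng.choice(len(others), 24,
                                                        replace=False)]
    out2 = kn.node_enrichment(idx, sel)
    assert out2.iloc[0]["node"] == rare


def test_node_enrichment_p_one_when_node_universal():
    g = _graph_from_edges(
        [("m1", "r1"), ("m2", "r1"), ("m3", "r1")],
        {"m1": "metabolite", "m2": "metabolite", "m3": "metabolite",
         "r1": "reaction"})
    idx = kn.build_path_index(g)
    out = kn.node_enrichment(idx, idx.pairs)
    assert out.iloc[0]["p"] == pytest.approx(1.0)


def test_rewire_preserves_degrees_and_detects_planted(default_path_index):
    idx = default_path_index
    pairs = idx.pairs
    counts = idx.node_pair_counts(pairs)
    rare = [v for v, c in sorted(counts.items(), key=lambda kv: kv[1])
            if 15 <= c <= 60][0]
    through = [p for p in pairs if idx.node_on_path(rare, *p)]
    others = [p for p in pairs if not idx.node_on_path(rare, *p)]
    rng = np.random.default_rng(2)
    cov = ([through[i] for i in rng.choice(len(through), 5, replace=False)]
           + [others[i] for i in rng.choice(len(others), 24, replace=False)])
    rw = kn.rewire_permutation(idx, cov, rare, n_perm=300, seed=3)
    # degree preservation is asserted inside every iteration; reaching here
    # with a sane null distribution means it held
    assert rw.observed == 5
    assert rw.null_mean < rw.observed
    assert rw.empirical_p < 0.05


def test_rewire_focal_on_every_pair_p_one():
    g = _graph_from_edges(
        [("m1", "r1"), ("m2", "r1"), ("m3", "r1"), ("m4", "r1")],
        {f"m{i}": "metabolite" for i in range(1, 5)} | {"r1": "reaction"})
    idx = kn.build_path_index(g)
    cov = [("m1", "m2"), ("m3", "m4")]
    rw = kn.rewire_permutation(idx, cov, "r1", n_perm=50, seed=4)
    assert rw.empirical_p == 1.0


def test_diffusion_scores(default_graph):
    g = default_graph
    empty = kn.diffusion_enrichment(g, [], n_perm=10, seed=0)
    assert np.allclose(empty["score"], 0.0)

    # seeds = all metabolite neighbours of one pathway node -> that pathway
    # node is the best-scoring pathway
    pwy = [p for p in g.nodes_of_class("pathway")
           if any(g.klass(v) == "metabolite" for v in g.g.neighbors(p))]
    target = pwy[0]
    seeds = [v for v in g.g.neighbors(target) if g.klass(v) == "metabolite"]
    out = kn.diffusion_enrichment(g, seeds, n_perm=300, seed=1)
    pw_rows = out[out["class"] == "pathway"].sort_values("p")
    assert pw_rows.iloc[0]["node"] == target

    # node-order invariance of the scores
    g2 = kn.HeteroGraph(nx.Graph(g.g.subgraph(sorted(g.g.nodes, reverse=True)).copy()))
    out2 = kn.diffusion_enrichment(g2, seeds, n_perm=10, seed=1)
    merged = out.set_index("node")["score"]
    merged2 = out2.set_index("node")["score"]
    np.testing.assert_allclose(merged.sort_index(), merged2.sort_index(),
                               atol=1e-9)
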