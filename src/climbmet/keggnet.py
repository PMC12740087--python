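"""Shortest-path enrichment on a heterogeneous metabolic graph.

The graph has typed nodes (metabolite, reaction, enzyme, pathway, module)
and undirected unweighted edges; metabolites never connect directly but
only through the other node classes, mirroring how compounds relate in a
KEGG-style reconstruction.  The analyses ask which non-metabolite nodes are
over-represented on the shortest paths connecting *covarying* metabolite
pairs, against the background of all mapped pairs:

* :class:`PathIndex` precomputes, per mapped metabolite, BFS distances and
  Brandes-style shortest-path counts; a node v lies on a shortest s-t path
  iff d(s,v) + d(v,t) = d(s,t), so membership never requires enumerating
  paths.  Path length is counted in intermediate nodes (d - 1), which is
  the natural "how many biological entities separate these compounds".
* :func:`path_length_enrichment`: are covarying pairs closer in the graph
  than all pairs?  Chi-square over length classes 1..5+.
* :func:`node_enrichment`: one-sided hypergeometric test per node, drawing
  the covarying pairs from the population of all mapped pairs of which A
  contain the node.
* :func:`rewire_permutation`: degree-preserving double-edge-swap null for a
  focal node, testing whether its enrichment reflects which metabolites are
  *paired* rather than which metabolites are merely present.
* :func:`diffusion_enrichment`: regularized-Laplacian heat diffusion from a
  seed metabolite set with an equal-size random-seed null, reported
  separately for pathway/module nodes.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

NODE_CLASSES = ("metabolite", "reaction", "enzyme", "pathway", "module")

__all__ = [
    "HeteroGraph",
    "load_graph",
    "PathIndex",
    "build_path_index",
    "path_length_enrichment",
    "node_enrichment",
    "RewireResult",
    "rewire_permutation",
    "diffusion_enrichment",
]


@dataclass
class HeteroGraph:
    """Typed, simple, undirected, unweighted graph."""

    g: nx.Graph

    def __post_init__(self) -> None:
        for n, d in self.g.nodes(data=True):
            if d.get("klass") not in NODE_CLASSES:
                raise ValueError(f"node {n!r} has invalid class {d.get('klass')!r}")
        bad = [
            (u, v)
            for u, v in self.g.edges
            if self.g.nodes[u]["klass"] == "metabolite"
            and self.g.nodes[v]["klass"] == "metabolite"
        ]
        if bad:
            raise ValueError(f"metabolite-metabolite edges are forbidden: {bad[:10]}")

    def klass(self, node) -> str:
        return self.g.nodes[node]["klass"]

    def nodes_of_class(self, klass: str) -> list:
        return [n for n, d in self.g.nodes(data=True) if d["klass"] == klass]

    @property
    def metabolites(self) -> list:
        return self.nodes_of_class("metabolite")

    def class_counts(self) -> dict:
        out = {k: 0 for k in NODE_CLASSES}
        for _, d in self.g.nodes(data=True):
            out[d["klass"]] += 1
        return out


def load_graph(nodes_path: str | Path, edges_path: str | Path) -> HeteroGraph:
    """Read a node-class table (node_id, class) and edge list (node_a,
    node_b); dangling edge endpoints are a hard error and
    metabolite-metabolite edges are rejected with the offending rows."""
    nodes = pd.read_csv(nodes_path, sep="\t")
    edges = pd.read_csv(edges_path, sep="\t")
    for cols, df, what in ((["node_id", "class"], nodes, nodes_path),
                           (["node_a", "node_b"], edges, edges_path)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{what}: missing columns {missing}")
    g = nx.Graph()
    for _, row in nodes.iterrows():
        g.add_node(row["node_id"], klass=row["class"])
    known = set(g.nodes)
    dangling = [
        (r.node_a, r.node_b)
        for r in edges.itertuples()
        if r.node_a not in known or r.node_b not in known
    ]
    if dangling:
        raise ValueError(f"edge endpoints missing from node table: {dangling[:10]}")
    g.add_edges_from(zip(edges["node_a"], edges["node_b"]))
    return HeteroGraph(g)


def _bfs_sigma(adj: list[list[int]], source: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """BFS distances and shortest-path counts (Brandes sigma) from source."""
    dist = np.full(n, -1, dtype=np.int32)
    sigma = np.zeros(n, dtype=float)
    dist[source] = 0
    sigma[source] = 1.0
    q = deque([source])
    while q:
        v = q.popleft()
        dv = dist[v]
        for w in adj[v]:
            if dist[w] < 0:
                dist[w] = dv + 1
                q.append(w)
            if dist[w] == dv + 1:
                sigma[w] += sigma[v]
    return dist, sigma


@dataclass
class PathIndex:
    """Per-pair shortest-path structure over the mapped metabolites.

    Distances are in edges; ``length`` in intermediate nodes (d - 1).
    Unreachable pairs carry infinite distance and are excluded from
    ``pairs`` and every downstream tally.
    """

    nodes: list
    node_klass: np.ndarray
    mapped: list
    dist: dict            # metabolite -> int32 array over nodes (-1 unreachable)
    sigma: dict           # metabolite -> float array of shortest-path counts
    _idx: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._idx = {n: i for i, n in enumerate(self.nodes)}

    @property
    def pairs(self) -> list[tuple]:
        """All mapped metabolite pairs with a connecting path."""
        out = []
        for a in range(len(self.mapped)):
            s = self.mapped[a]
            ds = self.dist[s]
            for b in range(a + 1, len(self.mapped)):
                t = self.mapped[b]
                if ds[self._idx[t]] >= 0:
                    out.append((s, t))
        return out

    def pair_distance(self, s, t) -> float:
        d = self.dist[s][self._idx[t]]
        return float("inf") if d < 0 else int(d)

    def pair_length(self, s, t) -> float:
        """Number of intermediate nodes on a shortest s-t path."""
        d = self.pair_distance(s, t)
        return d - 1 if np.isfinite(d) else float("inf")

    def pair_path_count(self, s, t) -> int:
        return int(self.sigma[s][self._idx[t]])

    def pair_nodes(self, s, t) -> set:
        """Nodes (excluding the endpoints) on >=1 shortest s-t path."""
        d = self.dist[s][self._idx[t]]
        if d < 0:
            return set()
        ds, dt = self.dist[s], self.dist[t]
        on = (ds >= 0) & (dt >= 0) & (ds + dt == d)
        on[self._idx[s]] = False
        on[self._idx[t]] = False
        return {self.nodes[i] for i in np.flatnonzero(on)}

    def node_on_path(self, v, s, t) -> bool:
        i = self._idx[v]
        d = self.dist[s][self._idx[t]]
        if d < 0 or v == s or v == t:
            return False
        return bool(self.dist[s][i] >= 0 and self.dist[t][i] >= 0
                    and self.dist[s][i] + self.dist[t][i] == d)

    def node_pair_counts(self, pairs) -> dict:
        """For each node, the number of given pairs whose shortest paths
        contain it."""
        total = np.zeros(len(self.nodes), dtype=int)
        for s, t in pairs:
            d = self.dist[s][self._idx[t]]
            if d < 0:
                continue
            ds, dt = self.dist[s], self.dist[t]
            on = (ds >= 0) & (dt >= 0) & (ds + dt == d)
            on[self._idx[s]] = False
            on[self._idx[t]] = False
            total += on
        return {self.nodes[i]: int(c) for i, c in enumerate(total) if c > 0}


def build_path_index(graph: HeteroGraph, mapped: list | None = None) -> PathIndex:
    """One BFS per mapped metabolite gives distances and path counts; node
    membership is then decided by the distance identity
    d(s,v) + d(v,t) = d(s,t), never by enumerating paths."""
    nodes = list(graph.g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    if mapped is None:
        mapped = graph.metabolites
    missing = [mn for mn in mapped if mn not in idx]
    if missing:
        raise ValueError(f"mapped metabolites absent from graph: {missing[:10]}")
    adj = [[idx[w] for w in graph.g.neighbors(n)] for n in nodes]
    dist, sigma = {}, {}
    for mn in mapped:
        d, s = _bfs_sigma(adj, idx[mn], len(nodes))
        dist[mn] = d
        sigma[mn] = s
    klass = np.array([graph.g.nodes[n]["klass"] for n in nodes])
    return PathIndex(nodes, klass, list(mapped), dist, sigma)


def _length_class(length: float, n_classes: int = 5) -> int:
    """Bin an intermediate-node path length into classes 1..n_classes (the
    last class is open-ended)."""
    return int(min(max(length, 1), n_classes))


def path_length_enrichment(
    index: PathIndex,
    selected_pairs,
    all_pairs=None,
    n_classes: int = 5,
) -> dict:
    """Are the selected pairs closer in the graph than all pairs?

    Lengths (intermediate nodes) are binned into classes 1..n_classes+
    and the selected-pair counts tested against the all-pair proportions
    by Pearson chi-square with df = classes - 1.  Classes empty in the
    background are merged from the tail (df adjusted, logged).
    """
    if all_pairs is None:
        all_pairs = index.pairs
    sel = [p for p in selected_pairs if np.isfinite(index.pair_length(*p))]
    if not sel:
        raise ValueError("no connected selected pairs")
    obs = np.zeros(n_classes)
    bg = np.zeros(n_classes)
    for s, t in sel:
        obs[_length_class(index.pair_length(s, t), n_classes) - 1] += 1
    for s, t in all_pairs:
        bg[_length_class(index.pair_length(s, t), n_classes) - 1] += 1
    # classes empty in the background are empty in the (nested) selection
    # too; merge them away from the tail and adjust df
    keepc = bg > 0
    if not keepc.all():
        warnings.warn("empty length classes merged; df adjusted")
        obs, bg = obs[keepc], bg[keepc]
    expected = bg / bg.sum() * obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    return {
        "chi2": chi2,
        "df": df,
        "p": float(stats.chi2.sf(chi2, df)),
        "observed": obs,
        "expected": expected,
        "background_counts": bg,
    }


def node_enrichment(
    index: PathIndex,
    covarying_pairs,
    background: str = "inclusive",
) -> pd.DataFrame:
    """Hypergeometric over-representation of each node on the shortest paths
    of the covarying pairs.

    For node v: a = covarying pairs whose shortest paths contain v, n =
    covarying pairs tested, A = mapped pairs containing v, N = all mapped
    pairs; p is the one-sided upper tail P(X >= a) for X ~
    Hypergeom(N, A, n).  The null population includes the covarying pairs
    by default (``background="exclusive"`` removes them).  The FDR family
    is the nodes on >=1 shortest path among the covarying pairs.
    """
    from .screens import bh_fdr

    cov = [tuple(p) for p in covarying_pairs]
    all_p = index.pairs
    all_set = {frozenset(p) for p in all_p}
    for p in cov:
        if frozenset(p) not in all_set:
            raise ValueError(f"covarying pair {p} is not a connected mapped pair")
    if background not in ("inclusive", "exclusive"):
        raise ValueError("background must be 'inclusive' or 'exclusive'")
    a_counts = index.node_pair_counts(cov)
    n = len(cov)
    rows = []
    if background == "inclusive":
        A_counts = index.node_pair_counts(all_p)
        N = len(all_p)
        for v, a in a_counts.items():
            A = A_counts[v]
            assert a <= min(n, A), "covarying-pair count exceeds background count"
            p = float(stats.hypergeom.sf(a - 1, N, A, n))
            rows.append({"node": v, "class": index.node_klass[index._idx[v]],
                         "a": a, "n": n, "A": A, "N": N, "p": p})
    else:
        # disjoint background: one-sided Fisher on the 2x2 table of
        # (contains node) x (covarying vs background-only)
        covset = {frozenset(p) for p in cov}
        bg_pairs = [p for p in all_p if frozenset(p) not in covset]
        A_counts = index.node_pair_counts(bg_pairs)
        N = len(bg_pairs)
        for v, a in a_counts.items():
            A = A_counts.get(v, 0)
            _, p = stats.fisher_exact([[a, n - a], [A, N - A]], alternative="greater")
            rows.append({"node": v, "class": index.node_klass[index._idx[v]],
                         "a": a, "n": n, "A": A, "N": N, "p": float(p)})
    out = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


@dataclass
class RewireResult:
    observed: int
    null_counts: np.ndarray
    null_mean: float
    empirical_p: float
    n_perm: int
    failed_swaps: int


def rewire_permutation(
    index: PathIndex,
    covarying_pairs,
    focal_node,
    n_perm: int = 10000,
    seed: int = 0,
) -> RewireResult:
    """Degree-preserving rewiring null for a focal node.

    The covarying pairs form a simple graph over the mapped metabolites;
    each permutation re-draws a simple graph with the identical degree
    sequence (double edge swaps, >= 10|E| mixing swaps from the observed
    network) and counts how many permuted pairs have the focal node on
    their shortest paths.  Empirical p uses the add-one convention.
    """
    cov = [tuple(p) for p in covarying_pairs]
    obs_graph = nx.Graph()
    obs_graph.add_nodes_from(index.mapped)
    obs_graph.add_edges_from(cov)
    if obs_graph.number_of_edges() < len(cov):
        raise ValueError("covarying pairs must form a simple graph (no duplicates)")
    degseq = sorted(d for _, d in obs_graph.degree)

    def count_focal(g: nx.Graph) -> int:
        return sum(index.node_on_path(focal_node, u, v) for u, v in g.edges)

    observed = count_focal(obs_graph)
    e = obs_graph.number_of_edges()
    nswap = max(10 * e, 1)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    failed = 0
    for b in range(n_perm):
        g = obs_graph.copy()
        try:
            if e >= 2:
                nx.double_edge_swap(g, nswap=nswap, max_tries=nswap * 100,
                                    seed=int(rng.integers(2**31 - 1)))
        except nx.NetworkXException:
            # try limit hit: swaps applied so far already preserve degrees
            failed += 1
        if sorted(d for _, d in g.degree) != degseq:
            raise RuntimeError("degree sequence not preserved by rewiring")
        counts[b] = count_focal(g)
    if failed > n_perm / 2:
        raise RuntimeError(f"rewiring failed in {failed}/{n_perm} permutations")
    if failed:
        warnings.warn(f"{failed} permutations hit the swap-try limit")
    p = (1 + int((counts >= observed).sum())) / (1 + n_perm)
    return RewireResult(observed, counts, float(counts.mean()), p, n_perm, failed)


def diffusion_enrichment(
    graph: HeteroGraph,
    seeds,
    n_perm: int = 1000,
    seed: int = 0,
    lam: float = 1.0,
) -> pd.DataFrame:
    """Regularized-Laplacian diffusion from a seed metabolite set.

    Heat b (1 on seeds) is diffused by solving (L + lam*I) s = b; per-node
    empirical p compares the observed score to scores under ``n_perm``
    random equal-size seed sets drawn from the metabolite nodes.  Pathway
    and module nodes are flagged so process-level hits can be read off
    directly.  Disconnected seeds diffuse within their own component (a
    property of the linear system).  Output metadata records the diffusion
    variant ("regularized-laplacian").
    """
    from .screens import bh_fdr

    nodes = list(graph.g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    seeds = list(seeds)
    for s in seeds:
        if s not in idx:
            raise ValueError(f"seed {s!r} not in graph")
    n = len(nodes)
    L = nx.laplacian_matrix(graph.g, nodelist=nodes).toarray().astype(float)
    K = np.linalg.inv(L + lam * np.eye(n))  # one inverse serves all permutations

    def score(seed_nodes) -> np.ndarray:
        b = np.zeros(n)
        for s in seed_nodes:
            b[idx[s]] = 1.0
        return K @ b

    obs = score(seeds)
    mets = [m for m in graph.metabolites]
    rng = np.random.default_rng(seed)
    if seeds:
        ge = np.ones(n, dtype=int)
        for _ in range(n_perm):
            draw = rng.choice(len(mets), size=len(seeds), replace=False)
            ge += score([mets[j] for j in draw]) >= obs
        pvals = ge / (1 + n_perm)
    else:
        pvals = np.ones(n)
    out = pd.DataFrame(
        {
            "node": nodes,
            "class": [graph.klass(v) for v in nodes],
            "score": obs,
            "p": pvals,
            "is_seed": [v in set(seeds) for v in nodes],
        }
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    out.attrs["method"] = "regularized-laplacian"
    out.attrs["lambda"] = lam
    return out
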