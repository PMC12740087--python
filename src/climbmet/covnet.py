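"""Pairwise correlation screening and per-fraction covariance networks.

A metabolite pair "covaries" when its Pearson correlation across samples is
significant; pairs whose covariance *pattern* depends on climbing fraction
(found by the interaction screen) are assembled into per-fraction networks:
an edge joins two metabolites when their within-fraction correlation is at
least nominally significant (p <= 0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "correlation_screen",
    "pearson_matrix",
    "CovNetwork",
    "build_fraction_network",
    "network_summary",
    "write_network",
]


def pearson_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided t-based p for columns of ``x``.

    Columns with zero variance yield NaN correlations.
    """
    n, m = x.shape
    if n < 4:
        raise ValueError("need at least 4 samples for correlation screening")
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0, ddof=1)
    good = sd > 0
    z = np.where(good, xc / np.where(good, sd, 1.0), np.nan)
    r = (z.T @ z) / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p


def correlation_screen(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation over all N(N-1)/2 metabolite pairs.

    Returns a DataFrame with columns ``i, k, met_i, met_k, r, p, q`` (BH q
    over the pairs with defined correlations); canonical ordering i < k.
    """
    from .screens import bh_fdr

    cols = list(matrix.columns)
    x = matrix.to_numpy(dtype=float)
    r, p = pearson_matrix(x)
    iu = np.triu_indices(len(cols), k=1)
    df = pd.DataFrame(
        {
            "i": iu[0],
            "k": iu[1],
            "met_i": [cols[a] for a in iu[0]],
            "met_k": [cols[b] for b in iu[1]],
            "r": r[iu],
            "p": p[iu],
        }
    )
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


@dataclass
class CovNetwork:
    """Simple undirected metabolite network for one fraction context."""

    graph: nx.Graph
    fraction: str          # "top", "bottom", ..., or "all"
    p_thresh: float

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}


def build_fraction_network(
    pairs: pd.DataFrame,
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    fraction: int | str,
    p_thresh: float = 0.05,
    stratify_age: bool = False,
) -> CovNetwork:
    """Network of interaction-significant pairs correlated within a fraction.

    ``pairs`` must carry ``met_i``/``met_k`` columns (e.g., the
    FDR-significant rows of the pair-interaction screen).  Samples of the
    given fraction are pooled over ages by default; with
    ``stratify_age=True`` an edge requires nominal significance at each age
    separately.  An empty network is a valid result.
    """
    from .fractionation import fraction_to_int, fraction_to_name

    f = fraction_to_int(fraction)
    mask = meta["fraction"].map(fraction_to_int).to_numpy() == f
    if mask.sum() < 4:
        raise ValueError(f"fraction {fraction!r} has fewer than 4 samples")
    sub = matrix.loc[mask]
    ages = meta.loc[mask, "age_week"].to_numpy()

    g = nx.Graph()
    for _, row in pairs.iterrows():
        a, b = row["met_i"], row["met_k"]
        if stratify_age:
            oks, rs = [], []
            for w in np.unique(ages):
                xs = sub.loc[ages == w, [a, b]].to_numpy()
                if len(xs) < 4:
                    oks.append(False)
                    continue
                r, p = stats.pearsonr(xs[:, 0], xs[:, 1])
                oks.append(p <= p_thresh)
                rs.append(r)
            if oks and all(oks):
                g.add_edge(a, b, r=float(np.mean(rs)), p=float(p_thresh))
        else:
            r, p = stats.pearsonr(sub[a], sub[b])
            if p <= p_thresh:
                g.add_edge(a, b, r=float(r), p=float(p))
    return CovNetwork(g, fraction_to_name(f), p_thresh)


def network_summary(net: CovNetwork, other: CovNetwork | None = None) -> dict:
    """Node/edge counts, degree table, and shared-edge count vs ``other``."""
    degrees = dict(net.graph.degree)
    out = {
        "fraction": net.fraction,
        "n_nodes": net.graph.number_of_nodes(),
        "n_edges": net.graph.number_of_edges(),
        "degrees": degrees,
        "max_degree_node": max(degrees, key=degrees.get) if degrees else None,
    }
    if other is not None:
        out["shared_edges"] = len(net.edges & other.edges)
    return out


def write_network(net: CovNetwork, edge_tsv: str | Path,
                  graphml: str | Path | None = None) -> None:
    rows = [
        {"node_a": min(u, v), "node_b": max(u, v),
         "r": d.get("r", np.nan), "p": d.get("p", np.nan)}
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "r", "p"]).sort_values(
        ["node_a", "node_b"]).to_csv(edge_tsv, sep="\t", index=False)
    if graphml is not None:
        nx.write_graphml(net.graph, graphml)


def all_pairs(names: list[str]) -> list[tuple[str, str]]:
    """Canonical enumeration of the N(N-1)/2 unordered pairs."""
    return list(combinations(names, 2))
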