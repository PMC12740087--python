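"""Tab-separated readers and writers for every pipeline input.

Fixed column contracts:

* survival TSV: ``fly_id, vial, fraction, entry_age, exit_age, event``
  (fraction 0..4 bottom..top; event 1=death, 0=censored)
* metabolome: abundance TSV (first column ``sample``, one column per
  metabolite) plus metadata TSV ``sample, age_week, fraction, replicate,
  batch, run_order``
* heterogeneous graph: node-class TSV ``node_id, class`` plus edge TSV
  ``node_a, node_b``
* bang assay TSV: ``vial, fraction, treatment, n_flies, n_alive_24h``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SURVIVAL_COLUMNS = ["fly_id", "vial", "fraction", "entry_age", "exit_age", "event"]
META_COLUMNS = ["age_week", "fraction", "replicate", "batch", "run_order"]
BANG_COLUMNS = ["vial", "fraction", "treatment", "n_flies", "n_alive_24h"]


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def write_survival_tsv(records: pd.DataFrame, path: str | Path) -> None:
    _require(records, SURVIVAL_COLUMNS, "survival table")
    records[SURVIVAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, SURVIVAL_COLUMNS, str(path))
    return df


def write_metabolome_tsv(matrix: pd.DataFrame, meta: pd.DataFrame,
                         matrix_path: str | Path, meta_path: str | Path) -> None:
    _require(meta, META_COLUMNS, "sample metadata")
    matrix.rename_axis("sample").to_csv(matrix_path, sep="\t")
    meta[META_COLUMNS].rename_axis("sample").to_csv(meta_path, sep="\t")


def read_metabolome_tsv(matrix_path: str | Path,
                        meta_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="sample")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    _require(meta, META_COLUMNS, str(meta_path))
    if not matrix.index.equals(meta.index):
        meta = meta.loc[matrix.index]
    return matrix, meta


def write_graph_tsv(graph, nodes_path: str | Path, edges_path: str | Path) -> None:
    """Write a HeteroGraph as a node-class table plus an edge list."""
    nodes = pd.DataFrame(
        {"node_id": list(graph.g.nodes),
         "class": [graph.g.nodes[n]["klass"] for n in graph.g.nodes]}
    ).sort_values("node_id")
    edges = pd.DataFrame(
        [(min(u, v), max(u, v)) for u, v in graph.g.edges],
        columns=["node_a", "node_b"],
    ).sort_values(["node_a", "node_b"])
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges.to_csv(edges_path, sep="\t", index=False)


def write_bang_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    _require(counts, BANG_COLUMNS, "bang-assay table")
    counts[BANG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bang_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, BANG_COLUMNS, str(path))
    return df
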