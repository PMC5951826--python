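"""Interaction-network I/O and probe-to-gene mapping.

Networks are plain :class:`networkx.Graph` objects: undirected, simple
(no self-loops, no parallel edges), node ids are strings, and edges may
carry an integer ``score`` attribute on the STRING 0-999 combined-score
scale. Loading drops self-interactions, collapses duplicate undirected
pairs (keeping the maximum score) and filters by a minimum score —
medium confidence 0.400 on STRING's scale, i.e. score >= 400, inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkLoadConfig:
    min_score: int = 400

    def __post_init__(self) -> None:
        if not 0 <= self.min_score <= 999:
            raise ValueError("min_score must be in [0, 999]")


class EdgeFileError(ValueError):
    """Malformed edge-list row (carries the 1-based line number)."""


def load_edges(path, config: NetworkLoadConfig | None = None) -> nx.Graph:
    """Load a STRING-style edge list into a simple undirected graph.

    The file is a TSV with two id columns and an optional integer score
    column. Edges scoring below ``min_score`` and self-edges are dropped;
    (a,b)/(b,a) and repeated rows collapse to one edge keeping the
    maximum score.
    """
    config = config or NetworkLoadConfig()
    graph = nx.Graph()
    with open(path) as handle:
        first = True
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if first and _looks_like_header(fields):
                first = False
                continue
            first = False
            if len(fields) < 2:
                raise EdgeFileError(f"line {lineno}: expected >= 2 tab-separated columns")
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise EdgeFileError(f"line {lineno}: empty node id")
            if len(fields) >= 3 and fields[2].strip():
                try:
                    score = int(float(fields[2]))
                except ValueError as exc:
                    raise EdgeFileError(f"line {lineno}: bad score {fields[2]!r}") from exc
            else:
                if config.min_score > 0:
                    raise EdgeFileError(
                        f"line {lineno}: score column required when min_score={config.min_score}"
                    )
                score = None
            if a == b:
                continue  # self-interaction
            if score is not None and score < config.min_score:
                continue
            if graph.has_edge(a, b):
                old = graph.edges[a, b].get("score")
                if score is not None and (old is None or score > old):
                    graph.edges[a, b]["score"] = score
            else:
                if score is None:
                    graph.add_edge(a, b)
                else:
                    graph.add_edge(a, b, score=score)
    return graph


def _looks_like_header(fields: list[str]) -> bool:
    if len(fields) < 3:
        return False
    try:
        int(float(fields[2]))
    except ValueError:
        return True
    return False


def write_edges(graph: nx.Graph, path) -> None:
    """Write the edge list as TSV (sorted, score column when present)."""
    rows = []
    for a, b, data in graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append((a, b, data.get("score")))
    rows.sort()
    with open(path, "w") as handle:
        handle.write("node_a\tnode_b\tscore\n")
        for a, b, score in rows:
            handle.write(f"{a}\t{b}\t{'' if score is None else score}\n")


def map_probes(probe_stats: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level statistics to gene level.

    ``probe_stats`` is indexed by probe id with at least a ``pvalue``
    column; ``mapping`` has columns ``probe`` and ``gene``. Probes with
    no mapped gene are dropped and counted; when several probes map to
    one gene, the probe with the smallest p-value carries the gene's
    statistics. The number of unmapped probes is logged and stored in
    ``result.attrs['n_unmapped_probes']``.
    """
    if mapping.empty:
        raise ValueError("empty probe-to-gene mapping")
    merged = probe_stats.reset_index(names="probe").merge(mapping, on="probe", how="left")
    unmapped = merged["gene"].isna()
    n_unmapped = int(probe_stats.index[~probe_stats.index.isin(mapping["probe"])].size)
    if n_unmapped:
        logger.info("%d probes could not be mapped to genes", n_unmapped)
    merged = merged.loc[~unmapped]
    # lowest p-value wins per gene; ties broken by probe id for determinism
    merged = merged.sort_values(["pvalue", "probe"], kind="mergesort")
    collapsed = merged.drop_duplicates("gene", keep="first").set_index("gene")
    collapsed = collapsed.sort_index()
    collapsed.attrs["n_unmapped_probes"] = n_unmapped
    return collapsed


def build_node_edge_tables(
    network: nx.Graph, stats: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables over the intersection of stats genes and network nodes.

    The node table carries (gene, pvalue, log2fc) for every gene in the
    intersection; the edge table keeps edges with both endpoints inside it.
    """
    common = sorted(set(stats.index) & set(network.nodes))
    if not common:
        raise ValueError(
            "no overlap between statistics genes and network nodes; "
            "check that both use the same identifier space"
        )
    nodes = pd.DataFrame(
        {"pvalue": stats.loc[common, "pvalue"], "log2fc": stats.loc[common, "log2fc"]},
        index=pd.Index(common, name="gene"),
    )
    keep = set(common)
    edges = [
        tuple(sorted((a, b))) + (data.get("score"),)
        for a, b, data in network.edges(data=True)
        if a in keep and b in keep
    ]
    edges.sort()
    edge_table = pd.DataFrame(edges, columns=["node_a", "node_b", "score"])
    return nodes, edge_table


def write_node_edge_files(nodes: pd.DataFrame, edges: pd.DataFrame, node_path, edge_path) -> None:
    nodes.to_csv(node_path, sep="\t", float_format="%.6g")
    edges.to_csv(edge_path, sep="\t", index=False)


def subgraph_from_edge_table(edges: pd.DataFrame) -> nx.Graph:
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        attrs = {}
        if "score" in edges.columns and pd.notna(row.score):
            attrs["score"] = int(row.score)
        graph.add_edge(row.node_a, row.node_b, **attrs)
    return graph
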