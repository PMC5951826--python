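"""Pathway annotation and shortest-path connector analysis.

Genes selected by differential expression or module discovery are
annotated against Wnt and Ras-MAPK gene sets (the Ras-MAPK set is the
union of the MAPK and Ras lists). "Connecting genes" between a source
gene (AURKA in the original analyses) and the annotated genes are the
interior nodes of unweighted all-shortest paths, restricted to a
subnetwork of selected genes, that carry no pathway annotation
themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class GeneSets:
    """Named gene sets with a composite Ras-MAPK union."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def union(self, *names: str) -> set[str]:
        out: set[str] = set()
        for name in names:
            out |= self.sets[name]
        return out


@dataclass
class ConnectorReport:
    source: str
    targets: list[str]
    unreachable: list[str]
    paths: dict[str, list[list[str]]]
    connecting_genes: set[str]


class GmtParseError(ValueError):
    pass


def load_gene_sets(path) -> GeneSets:
    """Read a GMT file: one set per line, name TAB description TAB members..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"line {lineno}: GMT requires name, description and >= 1 member"
                )
            name, desc, *members = fields
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise GmtParseError(f"line {lineno}: gene set {name!r} has no members")
            if name in sets:
                raise GmtParseError(f"line {lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSets(sets=sets, descriptions=descriptions)


def write_gene_sets(gene_sets: GeneSets, path) -> None:
    with open(path, "w") as handle:
        for name in sorted(gene_sets.sets):
            desc = gene_sets.descriptions.get(name, "")
            members = "\t".join(sorted(gene_sets.sets[name]))
            handle.write(f"{name}\t{desc}\t{members}\n")


def annotate_genes(
    genes,
    gene_sets: GeneSets,
    wnt: str = "Wnt",
    mapk: str = "MAPK",
    ras: str = "Ras",
) -> dict[str, str]:
    """Label each gene 'Wnt', 'Ras-MAPK', 'both' or 'none' by membership."""
    wnt_set = gene_sets.sets[wnt]
    ras_mapk = gene_sets.union(mapk, ras)
    labels = {}
    for gene in genes:
        in_wnt = gene in wnt_set
        in_rm = gene in ras_mapk
        if in_wnt and in_rm:
            labels[gene] = "both"
        elif in_wnt:
            labels[gene] = "Wnt"
        elif in_rm:
            labels[gene] = "Ras-MAPK"
        else:
            labels[gene] = "none"
    return labels


def selection_fraction(selected: set, annotated: set) -> tuple[int, int, int]:
    """(count annotated among selected, total selected, whole-percent fraction)."""
    total = len(selected)
    if total == 0:
        raise ValueError("empty selection")
    count = len(set(selected) & set(annotated))
    return count, total, round(100.0 * count / total)


def restrict_network(network: nx.Graph, keep) -> nx.Graph:
    """Induced subgraph on the kept genes (a copy)."""
    keep = set(keep)
    if not keep:
        raise ValueError("keep set is empty")
    present = keep & set(network.nodes)
    if not present:
        logger.warning("none of the kept genes occur in the network")
    return network.subgraph(present).copy()


def connectors(subnetwork: nx.Graph, source: str, annotated) -> ConnectorReport:
    """All-shortest-path connector genes from source to annotated genes.

    Paths are unweighted (minimum edge count); every shortest path is
    enumerated. A connecting gene is a path-interior node that is neither
    the source nor itself annotated. Unreachable targets are reported,
    not errors.
    """
    if source not in subnetwork:
        raise ValueError(f"source gene {source!r} absent from the subnetwork")
    annotated = set(annotated) - {source}
    targets = sorted(annotated & set(subnetwork.nodes))
    paths: dict[str, list[list[str]]] = {}
    unreachable = sorted(annotated - set(subnetwork.nodes))
    connecting: set[str] = set()
    for target in targets:
        try:
            target_paths = sorted(nx.all_shortest_paths(subnetwork, source, target))
        except nx.NetworkXNoPath:
            unreachable.append(target)
            continue
        paths[target] = target_paths
        for path in target_paths:
            connecting.update(
                v for v in path[1:-1] if v not in annotated and v != source
            )
    return ConnectorReport(
        source=source,
        targets=[t for t in targets if t in paths],
        unreachable=sorted(unreachable),
        paths=paths,
        connecting_genes=connecting,
    )


def shared_connectors(report_a: ConnectorReport, report_b: ConnectorReport) -> set[str]:
    """Connecting genes common to two conditions."""
    return report_a.connecting_genes & report_b.connecting_genes
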