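"""Pathway annotation fractions and connector-gene shortest paths.

Recomputes the published enrichment fractions (11/292, 8/154, 5/30,
9/31) from their printed numerators and denominators, annotates the
packaged 20 pathway genes, and runs the connector analysis on the
synthetic module: all shortest paths from a source gene to annotated
genes inside the module-plus-significant subnetwork. Writes
results/connectors.json.
"""

import json
from collections import Counter
from pathlib import Path

import pandas as pd

from modseeker import datasets, netio, modfind
from modseeker import pathway_links as pl

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "synthetic_dataset"
OUT = ROOT / "results"


def main() -> None:
    sets = datasets.load_pathway_sets()
    genes = sets.union("Wnt", "MAPK", "Ras")
    labels = pl.annotate_genes(genes, sets)
    counts = Counter(labels.values())
    print(f"packaged pathway genes: {len(genes)} total -> "
          f"{counts['Wnt']} Wnt-only, {counts['Ras-MAPK']} Ras-MAPK-only, {counts['both']} both")
    for count, total in ((11, 292), (8, 154), (5, 30), (9, 31)):
        sel = {f"g{i}" for i in range(total)}
        ann = {f"g{i}" for i in range(count)}
        _, _, pct = pl.selection_fraction(sel, ann)
        print(f"  enrichment {count}/{total} -> {pct}%")

    module = json.loads((OUT / "module.json").read_text())["heuristic"]["nodes"]
    graph = netio.load_edges(DATA / "edges.tsv", netio.NetworkLoadConfig(min_score=400))
    weights = pd.read_csv(OUT / "node_weights.tsv", sep="\t", index_col="gene")
    # synthetic annotation: treat the strongest-weighted module genes as
    # pathway members and connect from the module's top gene
    ranked = weights.loc[[g for g in module if g in weights.index]].sort_values(
        "weight", ascending=False
    )
    source = ranked.index[0]
    annotated = set(ranked.index[1 : 1 + max(3, len(ranked) // 3)])
    sub = pl.restrict_network(graph, set(module))
    report = pl.connectors(sub, source, annotated)
    print(f"connectors from {source} to {len(report.targets)} annotated module genes: "
          f"{sorted(report.connecting_genes)}")
    payload = {
        "annotation_counts": dict(counts),
        "source": source,
        "targets": report.targets,
        "connecting_genes": sorted(report.connecting_genes),
        "n_unreachable": len(report.unreachable),
    }
    (OUT / "connectors.json").write_text(json.dumps(payload, indent=2) + "\n")


if __name__ == "__main__":
    main()
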