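"""Packaged reference tables.

Two small text fixtures ship with the package:

* ``knockdown_shared_genes.tsv`` — the published table of 54 genes
  significantly deregulated in both the SW480 and Caco2 AURKA-knockdown
  experiments (p, q and log2 fold change per cell line).
* ``synthetic_pathway_sets.gmt`` — a synthetic stand-in for the KEGG Wnt /
  MAPK / Ras gene lists, restricted to the 20 reported pathway genes and
  reproducing their published Wnt / Ras-MAPK / both membership pattern.
"""

from importlib import resources

import pandas as pd

from modseeker.pathway_links import GeneSets, load_gene_sets


def _data_path(name: str):
    return resources.files("modseeker.data").joinpath(name)


def load_shared_knockdown_table() -> pd.DataFrame:
    """Table of the 54 genes deregulated in both knockdown cell lines.

    Returns a DataFrame indexed by gene symbol with columns
    ``sw480_p, sw480_q, sw480_log2fc, caco2_p, caco2_q, caco2_log2fc``
    and a ``gene_name`` annotation column.
    """
    with resources.as_file(_data_path("knockdown_shared_genes.tsv")) as path:
        table = pd.read_csv(path, sep="\t", index_col="gene")
    return table


def cell_line_stats(table: pd.DataFrame, cell_line: str) -> pd.DataFrame:
    """Extract one cell line's statistics as a gene-stats table.

    ``cell_line`` is ``"sw480"`` or ``"caco2"``. The result has the
    standard columns ``log2fc, pvalue, qvalue`` used throughout
    :mod:`modseeker.dea`.
    """
    key = cell_line.lower()
    if key not in {"sw480", "caco2"}:
        raise ValueError(f"unknown cell line {cell_line!r}")
    out = pd.DataFrame(
        {
            "log2fc": table[f"{key}_log2fc"],
            "pvalue": table[f"{key}_p"],
            "qvalue": table[f"{key}_q"],
        },
        index=table.index,
    )
    return out


def load_pathway_sets() -> GeneSets:
    """Synthetic stand-in Wnt / MAPK / Ras gene sets (GMT fixture)."""
    with resources.as_file(_data_path("synthetic_pathway_sets.gmt")) as path:
        return load_gene_sets(path)
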