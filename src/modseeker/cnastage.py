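"""Copy-number-gain stratification and the no-gain-vs-gain comparison.

Samples are labelled 'gain' when the overlap-length-weighted mean of
their copy-number segment means over a gene region reaches 0.4 (the
segment mean is the average tumour/normal log2 ratio), 'no-gain' below,
and 'no-call' when no segment overlaps the region. The group comparison
is run no-gain vs gain — deliberately reversed relative to the usual
tumour orientation so that its fold-change signs line up with a
knockdown experiment where the perturbed cells lose the gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from modseeker import dea

logger = logging.getLogger(__name__)

#: AURKA locus on chromosome 20 (genome build 19), 1-based inclusive
AURKA_REGION = ("20", 54_944_445, 54_967_393)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "segment_mean"]


@dataclass(frozen=True)
class CnaConfig:
    gain_threshold: float = 0.4
    region: tuple[str, int, int] = AURKA_REGION
    sig_adj_p: float = 1e-5

    def __post_init__(self) -> None:
        if self.gain_threshold <= 0:
            raise ValueError("gain_threshold must be positive")
        chrom, start, end = self.region
        if start > end or start < 1:
            raise ValueError(f"malformed region {self.region}")


def read_segments(path) -> pd.DataFrame:
    """Read a SEG-style TSV (sample, chrom, start, end, segment_mean)."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"segment table missing columns {missing}")
    if (table["start"] > table["end"]).any():
        bad = table.index[table["start"] > table["end"]][0]
        raise ValueError(f"segment row {bad}: start exceeds end")
    return table


def label_gain(segments: pd.DataFrame, config: CnaConfig | None = None) -> dict[str, str]:
    """Per-sample gain call over the configured region.

    The region statistic is the overlap-length-weighted mean of segment
    means across every segment intersecting the region (1-based inclusive
    coordinates). >= gain_threshold is 'gain', below is 'no-gain', no
    overlap is 'no-call'.
    """
    config = config or CnaConfig()
    chrom, start, end = config.region
    if (segments["start"] > segments["end"]).any():
        raise ValueError("segment table contains start > end rows")
    labels: dict[str, str] = {}
    for sample, rows in segments.groupby("sample"):
        on = rows[rows["chrom"].astype(str) == str(chrom)]
        ov_start = on["start"].clip(lower=start)
        ov_end = on["end"].clip(upper=end)
        lengths = (ov_end - ov_start + 1).clip(lower=0)
        total = lengths.sum()
        if total == 0:
            labels[sample] = "no-call"
            continue
        mean = float((on["segment_mean"] * lengths).sum() / total)
        labels[sample] = "gain" if mean >= config.gain_threshold else "no-gain"
    n_nocall = sum(1 for v in labels.values() if v == "no-call")
    if n_nocall:
        logger.info("%d samples had no segment over the region (no-call)", n_nocall)
    return labels


def gain_fraction(labels: dict[str, str]) -> tuple[int, int, float]:
    """(n_gain, n_labelled, percent to two decimals), no-calls excluded."""
    called = [v for v in labels.values() if v != "no-call"]
    if not called:
        raise ValueError("no callable samples")
    n_gain = sum(1 for v in called if v == "gain")
    percent = round(100.0 * n_gain / len(called), 2)
    return n_gain, len(called), percent


def group_dea(
    expression: pd.DataFrame,
    labels: dict[str, str],
    config: CnaConfig | None = None,
    dea_config: dea.DeaConfig | None = None,
) -> pd.DataFrame:
    """Moderated no-gain-vs-gain comparison (no-gain plays 'treated').

    A gene expressed higher in gain samples therefore gets a negative
    fold change, matching the knockdown orientation.
    """
    config = config or CnaConfig()
    usable = {s: v for s, v in labels.items() if v in ("gain", "no-gain") and s in expression.columns}
    table = dea.moderated_test(
        expression[list(usable)],
        pd.Series(usable),
        dea_config,
        treated="no-gain",
        control="gain",
    )
    table.attrs["note"] = "moderated two-group test reused for the copy-number stratification"
    return table


def significant_at_adj_p(table: pd.DataFrame, config: CnaConfig | None = None) -> set[tuple[str, str]]:
    """Genes with BH-adjusted p below the stage threshold, with direction."""
    config = config or CnaConfig()
    keep = table["qvalue"] < config.sig_adj_p
    return {
        (gene, "up" if fc >= 0 else "down")
        for gene, fc in zip(table.index[keep], table.loc[keep, "log2fc"])
    }


def region_direction_summary(
    stats: pd.DataFrame,
    gene_locations: pd.DataFrame,
    arm_region: tuple[str, int, int],
    config: CnaConfig | None = None,
) -> tuple[int, int, int, int]:
    """(n_arm_genes, n_significant, n_down, n_up) for genes in an arm region.

    ``gene_locations`` maps genes to (chrom, start, end); a gene is in
    the region when its interval intersects it.
    """
    config = config or CnaConfig()
    chrom, start, end = arm_region
    loc = gene_locations[gene_locations["chrom"].astype(str) == str(chrom)]
    inside = loc[(loc["end"] >= start) & (loc["start"] <= end)]
    arm_genes = [g for g in inside.index if g in stats.index]
    sub = stats.loc[arm_genes]
    sig = sub["qvalue"] < config.sig_adj_p
    n_down = int((sig & (sub["log2fc"] < 0)).sum())
    n_up = int((sig & (sub["log2fc"] >= 0)).sum())
    return len(arm_genes), int(sig.sum()), n_down, n_up


def overlap_compare(
    set_a: set[tuple[str, str]], set_b: set[tuple[str, str]]
) -> tuple[int, int, int]:
    """(n_overlap, n_same_direction, n_opposite) on shared gene ids."""
    dir_a = dict(set_a)
    dir_b = dict(set_b)
    shared = set(dir_a) & set(dir_b)
    same = sum(1 for g in shared if dir_a[g] == dir_b[g])
    return len(shared), same, len(shared) - same
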