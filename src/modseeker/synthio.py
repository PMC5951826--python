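"""Synthetic data with the statistical structure the analysis assumes.

The generator emits the four inputs the pipeline consumes:

* an undirected interaction network (uniform-random or preferential
  attachment), standing in for a STRING-scale graph;
* a connected "planted" module whose genes carry Beta(alpha, 1) p-values
  — exactly the signal component of the beta-uniform mixture the scoring
  stage fits — against a Uniform(0, 1) background;
* a replicate log2 expression matrix with the planted genes shifted in
  the treated group under Gaussian noise;
* per-sample copy-number segments with a gain subpopulation whose region
  segment mean exceeds the 0.4 call threshold.

Each sub-generator draws from its own stream derived from the master
seed by a fixed offset, so adding one generator never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from modseeker.cnastage import AURKA_REGION, SEG_COLUMNS

_P_FLOOR = 1e-300

# fixed sub-stream offsets from the master seed
_STREAM_NETWORK = 0
_STREAM_PLANT = 1
_STREAM_PVALUES = 2
_STREAM_EXPRESSION = 3
_STREAM_SEGMENTS = 4

NETWORK_MODELS = ("random-uniform-edges", "preferential-attachment")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: a 200-gene uniform-random network at edge probability 0.01
    (mean degree ~2, a sparse scaled-down interactome on which planted
    modules are identifiable), a planted connected module of 15 genes
    with Beta(0.2, 1) p-values, two replicates per group (as in the
    knockdown arrays) with a 1.0 log2 shift under 0.1-sd noise, and a
    66% gain subpopulation shifted by 0.58 — one extra copy in a diploid
    background, log2(3/2).
    """

    n_genes: int = 200
    network_model: str = "random-uniform-edges"
    edge_param: float = 0.01
    planted_module_size: int = 15
    signal_alpha: float = 0.2
    n_replicates_per_group: int = 2
    effect_size_log2: float = 1.0
    noise_sd: float = 0.1
    gain_fraction: float = 0.66
    gain_mean_shift: float = 0.58
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.network_model not in NETWORK_MODELS:
            raise ValueError(
                f"unknown network model {self.network_model!r}; choose from {NETWORK_MODELS}"
            )
        if self.network_model == "random-uniform-edges" and not 0.0 <= self.edge_param <= 1.0:
            raise ValueError("edge_param is an edge probability for random-uniform-edges")
        if self.network_model == "preferential-attachment" and not (
            float(self.edge_param).is_integer() and 1 <= self.edge_param < self.n_genes
        ):
            raise ValueError("edge_param is the integer attachment count for preferential-attachment")
        if not 0 <= self.planted_module_size <= self.n_genes:
            raise ValueError("planted_module_size must be in [0, n_genes]")
        if not 0.0 < self.signal_alpha < 1.0:
            raise ValueError("signal_alpha must be in (0, 1)")
        if self.n_replicates_per_group < 2:
            raise ValueError("n_replicates_per_group must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.gain_fraction <= 1.0:
            raise ValueError("gain_fraction must be in [0, 1]")
        if self.gain_mean_shift <= 0:
            raise ValueError("gain_mean_shift must be positive")


@dataclass
class SynthDataset:
    network: nx.Graph
    planted_nodes: set[str]
    pvalues: dict[str, float]
    expression: pd.DataFrame
    groups: pd.Series
    segments: pd.DataFrame
    config: SynthConfig = field(repr=False)
    seed: int = 0


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def generate_network(config: SynthConfig) -> nx.Graph:
    """Simple undirected graph with stable zero-padded string node ids."""
    rng = _rng(config.seed, _STREAM_NETWORK)
    n = config.n_genes
    if config.network_model == "random-uniform-edges":
        graph = nx.gnp_random_graph(n, config.edge_param, seed=rng)
    else:
        graph = nx.barabasi_albert_graph(n, int(config.edge_param), seed=rng)
    mapping = dict(zip(range(n), _gene_ids(n)))
    graph = nx.relabel_nodes(graph, mapping)
    graph.add_nodes_from(mapping.values())  # keep isolated genes
    return graph


def plant_module(network: nx.Graph, size: int, seed: int) -> set[str]:
    """Grow a connected module of exactly `size` nodes by seeded BFS.

    The start node is drawn uniformly among nodes whose component is
    large enough; neighbours are appended in shuffled breadth-first
    order.
    """
    if size == 0:
        return set()
    rng = _rng(seed, _STREAM_PLANT)
    components = [c for c in nx.connected_components(network) if len(c) >= size]
    if not components:
        largest = max((len(c) for c in nx.connected_components(network)), default=0)
        raise ValueError(
            f"no connected component can host a module of {size} nodes "
            f"(largest component has {largest})"
        )
    eligible = sorted(set().union(*components))
    start = eligible[int(rng.integers(len(eligible)))]
    selected = {start}
    frontier = sorted(set(network.neighbors(start)))
    while len(selected) < size:
        rng.shuffle(frontier)
        nxt = frontier.pop()
        if nxt in selected:
            continue
        selected.add(nxt)
        frontier.extend(sorted(set(network.neighbors(nxt)) - selected - set(frontier)))
    return selected


def generate_pvalues(
    network: nx.Graph, planted: set[str], signal_alpha: float, seed: int
) -> dict[str, float]:
    """One p-value per node: Beta(alpha, 1) for planted genes, uniform else."""
    if not 0.0 < signal_alpha < 1.0:
        raise ValueError("signal_alpha must be in (0, 1)")
    missing = set(planted) - set(network.nodes)
    if missing:
        raise ValueError(f"planted genes absent from the network: {sorted(missing)[:5]}")
    rng = _rng(seed, _STREAM_PVALUES)
    out = {}
    for gene in sorted(network.nodes):
        if gene in planted:
            p = float(rng.beta(signal_alpha, 1.0))
        else:
            p = float(rng.uniform())
        out[gene] = max(p, _P_FLOOR)
    return out


def generate_expression(
    config: SynthConfig, planted: set[str], seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x sample log2 matrix with the planted genes shifted when treated.

    Per-gene baselines are N(7, 1); treated samples of planted genes are
    shifted by ``effect_size_log2``; residual noise is N(0, noise_sd).
    Returns the matrix and a sample -> {'control', 'treated'} series.
    """
    rng = _rng(config.seed if seed is None else seed, _STREAM_EXPRESSION)
    genes = _gene_ids(config.n_genes)
    reps = config.n_replicates_per_group
    samples = [f"ctrl_{i + 1}" for i in range(reps)] + [f"trt_{i + 1}" for i in range(reps)]
    groups = pd.Series(["control"] * reps + ["treated"] * reps, index=samples)
    baseline = rng.normal(7.0, 1.0, size=config.n_genes)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, 2 * reps))
    matrix = baseline[:, None] + noise
    planted_rows = [i for i, g in enumerate(genes) if g in planted]
    matrix[np.ix_(planted_rows, range(reps, 2 * reps))] += config.effect_size_log2
    expression = pd.DataFrame(matrix, index=genes, columns=samples)
    return expression, groups


def generate_segments(
    config: SynthConfig,
    n_samples: int,
    region: tuple[str, int, int] = AURKA_REGION,
    seed: int | None = None,
) -> pd.DataFrame:
    """SEG-style table with a gain subpopulation over the region.

    Each sample contributes one segment spanning the region (with small
    random padding); gain samples centre on ``gain_mean_shift``, the
    rest on 0, both under N(0, noise_sd) noise.
    """
    chrom, start, end = region
    if start > end:
        raise ValueError(f"empty region {region}")
    rng = _rng(config.seed if seed is None else seed, _STREAM_SEGMENTS)
    rows = []
    for i in range(n_samples):
        sample = f"s{i + 1:04d}"
        is_gain = rng.uniform() < config.gain_fraction
        centre = config.gain_mean_shift if is_gain else 0.0
        mean = centre + rng.normal(0.0, config.noise_sd)
        pad_left = int(rng.integers(0, 5000))
        pad_right = int(rng.integers(0, 5000))
        rows.append(
            (sample, str(chrom), max(1, start - pad_left), end + pad_right, round(mean, 6))
        )
    return pd.DataFrame(rows, columns=SEG_COLUMNS)


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate all coupled pieces of one synthetic study."""
    network = generate_network(config)
    planted = plant_module(network, config.planted_module_size, config.seed)
    pvalues = generate_pvalues(network, planted, config.signal_alpha, config.seed)
    expression, groups = generate_expression(config, planted)
    segments = generate_segments(config, n_samples=100)
    return SynthDataset(
        network=network,
        planted_nodes=planted,
        pvalues=pvalues,
        expression=expression,
        groups=groups,
        segments=segments,
        config=config,
        seed=config.seed,
    )


def write_dataset(dataset: SynthDataset, outdir) -> None:
    """Serialise every piece as deterministic plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.expression.round(8).to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
    dataset.groups.rename("group").to_csv(outdir / "groups.tsv", sep="\t", index_label="sample")
    with open(outdir / "edges.tsv", "w") as handle:
        handle.write("node_a\tnode_b\tscore\n")
        for a, b in sorted(tuple(sorted(e)) for e in dataset.network.edges):
            handle.write(f"{a}\t{b}\t999\n")
    pd.Series(dataset.pvalues, name="pvalue").round(12).to_csv(
        outdir / "pvalues.tsv", sep="\t", index_label="gene"
    )
    dataset.segments.to_csv(outdir / "segments.tsv", sep="\t", index=False)
    truth = {
        "planted_nodes": sorted(dataset.planted_nodes),
        "seed": dataset.seed,
        "config": dataclasses.asdict(dataset.config),
    }
    with open(outdir / "truth.json", "w") as handle:
        json.dump(truth, handle, indent=2, sort_keys=True)
        handle.write("\n")
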