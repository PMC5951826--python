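"""Basic figures: a volcano plot and a module rendering helper."""

from __future__ import annotations

import numpy as np

from modseeker.dea import DeaConfig


def volcano(table, config: DeaConfig | None = None, ax=None):
    """Volcano plot of a gene-stats table (log2fc vs -log10 q)."""
    import matplotlib.pyplot as plt

    config = config or DeaConfig()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    q = np.maximum(table["qvalue"].to_numpy(), 1e-300)
    fc = table["log2fc"].to_numpy()
    sig = (q < config.q_threshold) & (np.abs(fc) >= config.log2fc_cut)
    colors = np.where(~sig, "0.6", np.where(fc > 0, "tab:blue", "tab:red"))
    ax.scatter(fc, -np.log10(q), s=8, c=colors, linewidths=0)
    ax.axhline(-np.log10(config.q_threshold), ls="--", lw=0.8, c="k")
    for x in (config.log2fc_cut, -config.log2fc_cut):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 q")
    return ax


def draw_module(graph, module, ax=None, seed: int = 0):
    """Draw a network with module membership and weight signs highlighted."""
    import matplotlib.pyplot as plt
    import networkx as nx

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sub = graph.subgraph(module.nodes)
    pos = nx.spring_layout(sub, seed=seed)
    colors = ["tab:blue" if module.node_weights.get(v, 0) > 0 else "tab:orange" for v in sub]
    nx.draw_networkx(sub, pos=pos, ax=ax, node_color=colors, node_size=250, font_size=6)
    ax.set_axis_off()
    return ax
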