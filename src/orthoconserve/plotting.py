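"""Plain diagnostic plots for interactivity profiles and set networks."""

from __future__ import annotations

from typing import Optional, Sequence

from .interactions import InteractionNetwork, InteractivityProfile

__all__ = ["plot_interactivity", "plot_set_network"]


def plot_interactivity(profiles: Sequence[InteractivityProfile], ax=None):
    """Bar plot of total within-set interactions per gene set."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.6 * len(profiles)), 3.2))
    labels = [p.set_label for p in profiles]
    totals = [p.total_edges for p in profiles]
    ax.bar(range(len(profiles)), totals, color="0.4")
    ax.set_xticks(range(len(profiles)))
    ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("within-set interactions")
    return ax


def plot_set_network(
    network: InteractionNetwork, gene_set, ax=None, seed: int = 0, labels: bool = True
):
    """Spring-layout drawing of the interactions inside one gene set."""
    import matplotlib.pyplot as plt
    import networkx as nx

    genes = sorted(frozenset(gene_set))
    sub = network.graph.subgraph(genes)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pos = nx.spring_layout(sub, seed=seed)
    nx.draw_networkx_edges(sub, pos, ax=ax, alpha=0.5)
    nx.draw_networkx_nodes(sub, pos, ax=ax, node_size=60, node_color="0.3")
    if labels:
        nx.draw_networkx_labels(sub, pos, ax=ax, font_size=6)
    ax.set_axis_off()
    return ax
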