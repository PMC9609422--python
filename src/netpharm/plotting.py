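"""Small matplotlib views of pipeline results.

Figures are conveniences over the JSON/TSV artefacts, not analysis
outputs; matplotlib is imported lazily so headless pipeline runs never
touch it.
"""

from __future__ import annotations

from pathlib import Path

from .graph_core import PPINetwork
from .mcode import MCODECluster
from .setops import VennResult


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_degree_distribution(net: PPINetwork, path: str | Path) -> None:
    """Log-log degree histogram; scale-free networks appear near-linear."""
    plt = _plt()
    degrees = [d for _, d in net.graph.degree()]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(degrees, bins=30)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("degree")
    ax.set_ylabel("nodes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cluster_scores(clusters: list[MCODECluster], path: str | Path) -> None:
    """Bar chart of MCODE cluster scores in rank order."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    ranks = list(range(1, len(clusters) + 1))
    ax.bar(ranks, [c.score for c in clusters])
    ax.set_xlabel("cluster rank")
    ax.set_ylabel("score (density x nodes)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_venn_counts(result: VennResult, path: str | Path) -> None:
    """Labelled bar chart of Venn region counts (2- or 3-set)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    sigs = sorted(result.region_counts)
    labels = [
        "&".join(
            lab for lab, bit in zip(result.set_labels, sig) if bit == "1"
        ) or "none"
        for sig in sigs
    ]
    ax.bar(range(len(sigs)), [result.region_counts[s] for s in sigs])
    ax.set_xticks(range(len(sigs)), labels, rotation=30, ha="right")
    ax.set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
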