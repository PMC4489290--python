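"""Summary measurements of an interactome.

Reported per network: number of proteins, number of PPIs, connected
components, average clustering coefficient, the node degree histogram
and (for weighted networks) the edge-weight histogram. Self-loops count
as PPIs and add two to their node's degree, but are excluded from the
clustering computation; a node with fewer than two neighbors contributes
zero to the clustering average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from ppinet.consolidate import Interactome
from ppinet.scoring import WEIGHT_BINS, weight_histogram


@dataclass
class NetworkStats:
    n_proteins: int = 0
    n_ppis: int = 0
    n_self_loops: int = 0
    n_components: int = 0
    avg_clustering: float = 0.0
    degree_histogram: dict[int, int] = field(default_factory=dict)
    weight_histogram: list[int] | None = None

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            "measure\tvalue",
            f"proteins\t{self.n_proteins}",
            f"ppis\t{self.n_ppis}",
            f"self_loops\t{self.n_self_loops}",
            f"connected_components\t{self.n_components}",
            f"avg_clustering_coefficient\t{self.avg_clustering:.6g}",
        ]
        for deg in sorted(self.degree_histogram):
            lines.append(f"degree_{deg}\t{self.degree_histogram[deg]}")
        if self.weight_histogram is not None:
            for i, count in enumerate(self.weight_histogram):
                lines.append(
                    f"weight_({WEIGHT_BINS[i]:.2f},{WEIGHT_BINS[i + 1]:.2f}]"
                    f"\t{count}")
        Path(path).write_text("\n".join(lines) + "\n")


def compute_stats(net: Interactome) -> NetworkStats:
    """Compute the summary measurements of an interactome.

    Components come from traversal of the undirected graph (self-loops do
    not affect them). Local clustering is 2*T(v) / (d(v)*(d(v)-1)) with
    T(v) the triangles through v on the simple graph without self-loops,
    and the average runs over ALL nodes, scoring 0 where d(v) < 2. An
    empty network reports all-zero statistics by convention.
    """
    g = net.to_networkx()
    n_self = sum(1 for (a, b), _ in net.edges() if a == b)
    stats = NetworkStats(
        n_proteins=g.number_of_nodes(),
        n_ppis=len(net),
        n_self_loops=n_self,
    )
    if g.number_of_nodes() == 0:
        return stats
    stats.n_components = nx.number_connected_components(g)
    simple = g.copy()
    simple.remove_edges_from(nx.selfloop_edges(simple))
    stats.avg_clustering = (nx.average_clustering(simple)
                            if simple.number_of_nodes() else 0.0)
    degrees: dict[int, int] = {}
    for _, d in g.degree():  # a self-loop contributes 2 to its node
        degrees[d] = degrees.get(d, 0) + 1
    stats.degree_histogram = degrees
    weights = [ev.weight for _, ev in net.edges() if ev.weight is not None]
    if weights:
        stats.weight_histogram = weight_histogram(weights)
    return stats


def plot_distributions(stats: NetworkStats, outdir: str | Path,
                       prefix: str = "network") -> list[Path]:
    """Write degree-distribution and (if weighted) weight-distribution
    plots as PNG files; returns the paths written."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    fig, ax = plt.subplots(figsize=(5, 3.5))
    degs = sorted(stats.degree_histogram)
    ax.bar(degs, [stats.degree_histogram[d] for d in degs], color="#4878a8")
    ax.set_xlabel("node degree")
    ax.set_ylabel("number of proteins")
    ax.set_title("Degree distribution")
    fig.tight_layout()
    path = outdir / f"{prefix}_degree_distribution.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    written.append(path)

    if stats.weight_histogram is not None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        centers = [(WEIGHT_BINS[i] + WEIGHT_BINS[i + 1]) / 2
                   for i in range(len(stats.weight_histogram))]
        ax.bar(centers, stats.weight_histogram, width=0.045, color="#a85048")
        ax.set_xlabel("interaction weight")
        ax.set_ylabel("number of PPIs")
        ax.set_title("PPI weight distribution")
        fig.tight_layout()
        path = outdir / f"{prefix}_weight_distribution.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
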