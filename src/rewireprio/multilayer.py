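"""Multilayer network over stage-wise top-ranked genes.

Each developmental stage contributes one layer: the induced subnetwork of
that stage's rewiring network (WGDCN) over its top-ranked genes.
Interlayer edges join the same gene appearing in two different layers.
Per-layer topology statistics (density, average degree, average path
length over connected pairs, average clustering) and the Jaccard overlap
between stage gene sets quantify how rewiring patterns shift across
development.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LayerStats:
    stage: int
    n_nodes: int
    n_edges: int
    density: float
    avg_degree: float
    avg_path_length: float
    avg_clustering: float


@dataclass
class MultilayerNetwork:
    """Stage-indexed layers plus same-gene interlayer edges."""

    layers: list            # list of (stage, networkx.Graph)
    interlayer_edges: list  # list of ((gene, stage_i), (gene, stage_j))

    def to_networkx(self) -> nx.Graph:
        """Flatten to a simple graph on (gene, stage) nodes; intralayer
        edges keep their rewiring weight, nodes carry gene/layer attributes."""
        g = nx.Graph()
        for stage, layer in self.layers:
            for node in layer.nodes:
                g.add_node(f"{node}@{stage}", gene=str(node), layer=int(stage),
                           **{k: v for k, v in layer.nodes[node].items()})
            for u, v, d in layer.edges(data=True):
                g.add_edge(f"{u}@{stage}", f"{v}@{stage}",
                           weight=float(d.get("weight", 1.0)), kind="intra")
        for (gene, si), (_, sj) in self.interlayer_edges:
            g.add_edge(f"{gene}@{si}", f"{gene}@{sj}", kind="inter")
        return g


def layer_subnetwork(net: nx.Graph, genes) -> nx.Graph:
    """Induced subgraph of a WGDCN over a gene list, weights preserved.

    Requested genes absent from the network are skipped with a warning.
    """
    genes = list(genes)
    present = [g for g in genes if g in net]
    missing = [g for g in genes if g not in net]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) not in network, skipped: {missing[:5]}",
                      stacklevel=2)
    sub = nx.Graph(net.subgraph(present))
    sub.graph.update(net.graph)
    return sub


def assemble_multilayer(layers) -> MultilayerNetwork:
    """Stack per-stage subnetworks and add same-gene interlayer edges."""
    layers = list(layers)
    if len(layers) < 2:
        raise ValueError("need at least 2 layers")
    inter = []
    for (si, gi), (sj, gj) in itertools.combinations(layers, 2):
        shared = set(gi.nodes) & set(gj.nodes)
        for gene in sorted(shared, key=str):
            inter.append(((gene, si), (gene, sj)))
    logger.info("multilayer network: %d layers, %d interlayer edges", len(layers), len(inter))
    return MultilayerNetwork(layers=layers, interlayer_edges=inter)


def layer_stats(net: nx.Graph, stage: int | None = None) -> LayerStats:
    """Unweighted topology statistics of one layer.

    Average path length is the mean shortest-path distance over connected
    node pairs only (0 if no pair is connected); average clustering counts
    degree < 2 nodes as 0.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0
    avg_degree = 2.0 * e / n
    total, pairs = 0.0, 0
    for comp in nx.connected_components(net):
        if len(comp) < 2:
            continue
        sub = net.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1  # exclude self
    avg_path = total / pairs if pairs else 0.0
    avg_clust = nx.average_clustering(net) if n else 0.0
    if stage is None:
        stage = int(net.graph.get("stage", 0))
    return LayerStats(stage=stage, n_nodes=n, n_edges=e, density=density,
                      avg_degree=avg_degree, avg_path_length=avg_path,
                      avg_clustering=avg_clust)


def layer_stats_table(mln: MultilayerNetwork) -> pd.DataFrame:
    rows = [layer_stats(g, stage=s).__dict__ for s, g in mln.layers]
    return pd.DataFrame(rows)


def jaccard_overlap(sets) -> np.ndarray:
    """Pairwise Jaccard overlap |A_i ∩ A_j| / |A_i ∪ A_j| between gene sets.

    Symmetric with unit diagonal for non-empty sets; the 0/0 case of two
    empty sets is defined as 0 with a warning.
    """
    sets = [set(s) for s in sets]
    if not sets:
        raise ValueError("need at least one set")
    k = len(sets)
    out = np.zeros((k, k))
    warned = False
    for i in range(k):
        for j in range(i, k):
            union = sets[i] | sets[j]
            if not union:
                if not warned:
                    warnings.warn("overlap of two empty sets defined as 0", stacklevel=2)
                    warned = True
                val = 0.0
            else:
                val = len(sets[i] & sets[j]) / len(union)
            out[i, j] = out[j, i] = val
    return out
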