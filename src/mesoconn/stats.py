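"""Global network structure: bow-tie decomposition, centrality, efficiency.

Shortest paths are topological throughout (every link has length 1, even on
weighted networks): distance counts the number of links that must be
traversed, matching how path length is used in connectome analyses of
signal propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io import Connectome

__all__ = ["BowTie", "bow_tie", "betweenness", "efficiency", "degree_profile", "DegreeProfile"]


@dataclass
class BowTie:
    """Disjoint, exhaustive decomposition of a directed network.

    ``scc`` is the largest strongly connected component; ``in_`` the nodes
    that reach it; ``out`` the nodes reachable from it; everything else
    (including tendrils and isolated nodes) is ``disconnected``.
    """

    scc: set[str]
    in_: set[str]
    out: set[str]
    disconnected: set[str]

    @property
    def sizes(self) -> tuple[int, int, int, int]:
        return (len(self.scc), len(self.in_), len(self.out), len(self.disconnected))


def bow_tie(net: Connectome) -> BowTie:
    """Decompose the directed network into SCC, IN, OUT and the rest."""
    g = net.graph
    if g.number_of_nodes() == 0:
        return BowTie(set(), set(), set(), set())
    scc = max(nx.strongly_connected_components(g), key=lambda c: (len(c), sorted(c)))
    rep = next(iter(scc))
    reachable = nx.descendants(g, rep) | {rep}
    reaching = nx.ancestors(g, rep) | {rep}
    out = reachable - scc
    in_ = reaching - scc
    disconnected = set(g) - scc - in_ - out
    return BowTie(set(scc), in_, out, disconnected)


def betweenness(net: Connectome, directed: bool = True) -> pd.Series:
    """Betweenness centrality: for each node the summed fraction of
    shortest paths between all other node pairs passing through it.

    Unnormalized; topological edge lengths. ``directed=False`` collapses
    the network to its undirected skeleton first.
    """
    g: nx.Graph | nx.DiGraph = net.graph
    if not directed:
        g = g.to_undirected()
    bc = nx.betweenness_centrality(g, normalized=False, weight=None)
    return pd.Series(bc, name="betweenness").sort_index()


def efficiency(net: Connectome) -> float:
    """Communication efficiency: mean of 1/d over all ordered node pairs.

    Disconnected pairs contribute 0, so the measure is finite on
    disconnected networks. Returns a value in [0, 1].
    """
    g = net.graph
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


@dataclass
class DegreeProfile:
    """Degree-correlation summary of a network."""

    assortativity: float
    knn: pd.DataFrame  # columns: k, knn_mean, n_nodes
    degree_ccdf: pd.DataFrame  # columns: k, ccdf
    strength_in_ccdf: pd.DataFrame
    strength_out_ccdf: pd.DataFrame


def _ccdf(values: np.ndarray) -> pd.DataFrame:
    values = np.sort(np.asarray(values, dtype=float))
    uniq = np.unique(values)
    frac = [(values >= v).mean() for v in uniq]
    return pd.DataFrame({"value": uniq, "ccdf": frac})


def degree_profile(net: Connectome) -> DegreeProfile:
    """Assortativity, neighbor-degree curve and cumulative distributions.

    Assortativity is the Pearson correlation of total degrees (k_in +
    k_out) across the two ends of every directed edge. knn(k) is the mean,
    over nodes of total degree k, of the average total degree of each
    node's unique neighbors (in- and out-neighbors combined).
    """
    g = net.graph
    if g.number_of_edges() < 2:
        raise ValueError("need at least 2 edges")
    k = {n: g.in_degree(n) + g.out_degree(n) for n in g}
    ends = np.array([(k[u], k[v]) for u, v in g.edges()], dtype=float)
    if np.std(ends[:, 0]) == 0 or np.std(ends[:, 1]) == 0:
        r = float("nan")
    else:
        r = float(pearsonr(ends[:, 0], ends[:, 1])[0])

    rows = []
    for n in g:
        nbrs = set(g.successors(n)) | set(g.predecessors(n))
        if not nbrs:
            continue
        rows.append((k[n], np.mean([k[m] for m in nbrs])))
    knn_df = (
        pd.DataFrame(rows, columns=["k", "knn"])
        .groupby("k")
        .agg(knn_mean=("knn", "mean"), n_nodes=("knn", "size"))
        .reset_index()
    )

    s_in = np.array([net.strength_in(n) for n in g])
    s_out = np.array([net.strength_out(n) for n in g])
    return DegreeProfile(
        assortativity=r,
        knn=knn_df,
        degree_ccdf=_ccdf(np.array(list(k.values()))),
        strength_in_ccdf=_ccdf(s_in),
        strength_out_ccdf=_ccdf(s_out),
    )
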