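"""Degree-preserving edge-swap null models and ensemble summaries.

A randomized replicate is built by repeatedly picking two edges
(a -> b, c -> d) and rewiring them to (a -> d, c -> b); the swap is aborted
when it would create a self-loop or an edge that already exists, so the
replicate stays a simple graph with every node's in- and out-degree
unchanged. Gap junctions, being symmetric, are swapped as undirected pairs
so that symmetry is preserved; the combined network is randomized channel
by channel and recombined. A modularity-constrained variant additionally
requires both edges to join the same ordered pair of modules, which
preserves every node's module-resolved degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np

from .io import Connectome
from .modularity import Partition

__all__ = [
    "EnsembleSummary",
    "degree_preserving_rewire",
    "constrained_rewire",
    "ensemble_stat",
]

#: attempted swaps per replicate, as a multiple of the channel's edge count
SWAP_FACTOR = 10


@dataclass
class EnsembleSummary:
    """Empirical value of a statistic against its randomized ensemble."""

    statistic: str
    empirical: float
    mean: float
    sd: float
    z: float
    n: int
    seed: int
    degenerate: bool = False  # sd == 0: z reported as 0 and flagged


def _swap_directed(
    g: nx.DiGraph,
    rng: np.random.Generator,
    n_attempts: int,
    classes=None,
    forbidden: frozenset = frozenset(),
) -> nx.DiGraph:
    g = g.copy()
    movable = [e for e in g.edges() if e not in forbidden]
    if classes is None:
        pools = [movable]
    else:
        by_class: dict = {}
        for u, v in movable:
            by_class.setdefault((classes[u], classes[v]), []).append((u, v))
        pools = list(by_class.values())
    weights = np.array([len(p) for p in pools], dtype=float)
    if weights.sum() < 2:
        warnings.warn("fewer than 2 swappable edges; returning input unchanged")
        return g
    weights /= weights.sum()
    for _ in range(n_attempts):
        pool = pools[rng.choice(len(pools), p=weights)]
        if len(pool) < 2:
            continue
        i, j = rng.choice(len(pool), size=2, replace=False)
        (a, b), (c, d) = pool[i], pool[j]
        if a == d or c == b or b == d or a == c:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        if (a, d) in forbidden or (c, b) in forbidden:
            continue
        wab = g[a][b]["weight"]
        wcd = g[c][d]["weight"]
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d, weight=wab)
        g.add_edge(c, b, weight=wcd)
        pool[i] = (a, d)
        pool[j] = (c, b)
    return g


def _swap_undirected(
    g: nx.Graph,
    rng: np.random.Generator,
    n_attempts: int,
    classes=None,
    forbidden: frozenset = frozenset(),
) -> nx.Graph:
    g = g.copy()
    movable = [
        e for e in g.edges() if tuple(sorted(e)) not in forbidden
    ]
    if classes is None:
        pools = [movable]
    else:
        by_class: dict = {}
        for u, v in movable:
            key = tuple(sorted((classes[u], classes[v])))
            by_class.setdefault(key, []).append((u, v))
        pools = list(by_class.values())
    weights = np.array([len(p) for p in pools], dtype=float)
    if weights.sum() < 2:
        warnings.warn("fewer than 2 swappable edges; returning input unchanged")
        return g
    weights /= weights.sum()
    for _ in range(n_attempts):
        pool = pools[rng.choice(len(pools), p=weights)]
        if len(pool) < 2:
            continue
        i, j = rng.choice(len(pool), size=2, replace=False)
        (a, b), (c, d) = pool[i], pool[j]
        if classes is not None:
            # orient so the swap stays inside the unordered class
            if classes[a] != classes[c]:
                c, d = d, c
            if classes[a] != classes[c]:
                continue
        elif rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        if (
            tuple(sorted((a, d))) in forbidden
            or tuple(sorted((c, b))) in forbidden
        ):
            continue
        wab = g[a][b]["weight"]
        wcd = g[c][d]["weight"]
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d, weight=wab)
        g.add_edge(c, b, weight=wcd)
        pool[i] = (a, d)
        pool[j] = (c, b)
    return g


def _rewire(
    net: Connectome, seed: int, n_swaps: int | None, classes: dict | None
) -> Connectome:
    if net.L < 2:
        warnings.warn("network has fewer than 2 edges; returning input unchanged")
        return net
    if classes is not None and len(set(classes.values())) == 1:
        classes = None  # single-module constraint is vacuous
    rng = np.random.default_rng(seed)
    syn = net.syn
    gap = net.gap
    # Edges whose node pair is also linked in the other channel are frozen,
    # and swaps may not create new cross-channel overlaps: the channels then
    # stay independently simple and the combined view's in/out degree
    # sequence is preserved exactly, not just per channel.
    gap_pairs = frozenset().union(
        *[{(u, v), (v, u)} for u, v in gap.edges()] or [frozenset()]
    )
    if syn.number_of_edges() >= 2:
        n = n_swaps if n_swaps is not None else SWAP_FACTOR * syn.number_of_edges()
        syn = _swap_directed(syn, rng, n, classes, forbidden=gap_pairs)
    # overlap avoidance for the gap channel uses the post-rewire syn edges
    syn_pairs = frozenset(
        tuple(sorted((u, v))) for u, v in syn.edges()
    )
    if gap.number_of_edges() >= 2:
        n = n_swaps if n_swaps is not None else SWAP_FACTOR * gap.number_of_edges()
        gap = _swap_undirected(gap, rng, n, classes, forbidden=syn_pairs)
    return Connectome(net.neurons, gap, syn, mode=net.mode, weighted=net.weighted)


def degree_preserving_rewire(
    net: Connectome, seed: int, n_swaps: int | None = None
) -> Connectome:
    """One randomized replicate with every in/out degree preserved.

    ``n_swaps`` is the number of attempted swaps per channel (default
    ``10 x`` the channel's edge count). Weights travel with their edges, so
    the total weight W is conserved.
    """
    return _rewire(net, seed, n_swaps, classes=None)


def constrained_rewire(
    net: Connectome, partition: Partition, seed: int, n_swaps: int | None = None
) -> Connectome:
    """Degree- and modularity-preserving replicate.

    Swaps only exchange edges joining the same ordered pair of modules, so
    besides the degree sequences, every node's number of links to each
    module — and hence the whole intra/inter-module link structure — is
    preserved.
    """
    missing = [n for n in net.neurons if n not in partition.assignment]
    if missing:
        raise ValueError("partition missing node(s): " + ", ".join(missing[:5]))
    return _rewire(net, seed, n_swaps, classes=dict(partition.assignment))


def ensemble_stat(
    net: Connectome,
    statistic: Callable[[Connectome], float],
    n: int = 100,
    seed: int = 0,
    mode: str = "degree",
    partition: Partition | None = None,
    name: str | None = None,
) -> EnsembleSummary:
    """Empirical value, ensemble mean/sd and z-score of a scalar statistic.

    ``mode`` is ``"degree"`` (plain degree-preserving) or ``"constrained"``
    (degree- and modularity-preserving; requires ``partition``).
    Reproducible for a fixed seed: replicate i uses seed ``seed + i``.
    """
    if mode not in ("degree", "constrained"):
        raise ValueError(f"unknown rewire mode {mode!r}")
    if mode == "constrained" and partition is None:
        raise ValueError("constrained mode requires a partition")
    empirical = float(statistic(net))
    values = []
    for i in range(n):
        rep_seed = int(seed) + i
        rep = (
            degree_preserving_rewire(net, rep_seed)
            if mode == "degree"
            else constrained_rewire(net, partition, rep_seed)
        )
        values.append(float(statistic(rep)))
    arr = np.array(values)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    degenerate = sd == 0.0
    z = 0.0 if degenerate else (empirical - mean) / sd
    return EnsembleSummary(
        statistic=name or getattr(statistic, "__name__", "statistic"),
        empirical=empirical,
        mean=mean,
        sd=sd,
        z=z,
        n=n,
        seed=int(seed),
        degenerate=degenerate,
    )
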