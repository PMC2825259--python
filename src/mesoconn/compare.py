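"""Comparing partitions and neuron groups: overlaps, NMI, modular spectra.

A neuron group (a ganglion, a functional circuit, or a module of a second
partition) is decomposed over the M modules of an optimal partition into a
fraction vector — its *modular spectrum*. Euclidean distance between two
spectra places groups in an abstract M-dimensional "modular" space.
Agreement between two whole partitions is quantified by normalized mutual
information computed from their overlap (contingency) matrix,

.. math:: NMI = \\frac{-2 \\sum_{ij} N_{ij}
          \\ln(N_{ij} n / N_{i.} N_{.j})}
          {\\sum_i N_{i.} \\ln(N_{i.}/n) + \\sum_j N_{.j} \\ln(N_{.j}/n)},

which is 1 for identical partitions and 0 for independent ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.stats import pearsonr

from .io import Connectome
from .modularity import Partition

__all__ = [
    "OverlapMatrix",
    "GroupSpectrum",
    "overlap_matrix",
    "nmi",
    "group_spectrum",
    "modular_distance",
    "module_summary",
    "group_distance_matrices",
    "GroupDistances",
    "linkage_to_newick",
    "dendrogram_path_lengths",
]


@dataclass
class OverlapMatrix:
    """Contingency counts of groups (rows) against modules (columns)."""

    counts: pd.DataFrame

    @property
    def row_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.values.sum())


@dataclass
class GroupSpectrum:
    """Fraction of a group's members falling in each module."""

    label: str
    fractions: np.ndarray
    size: int


def _as_groups(obj) -> dict:
    """Accept either a Partition or a mapping name -> member set."""
    if isinstance(obj, Partition):
        return {m: members for m, members in sorted(obj.modules().items())}
    return dict(obj)


def overlap_matrix(groups, p: Partition) -> OverlapMatrix:
    """Count group members per module; members must be partitioned nodes."""
    groups = _as_groups(groups)
    module_labels = sorted(set(p.assignment.values()))
    unknown = sorted(
        {m for members in groups.values() for m in members if m not in p.assignment}
    )
    if unknown:
        raise ValueError("group member(s) not in partition: " + ", ".join(unknown))
    counts = pd.DataFrame(
        0, index=list(groups), columns=module_labels, dtype=int
    )
    for gname, members in groups.items():
        for m in members:
            counts.loc[gname, p.assignment[m]] += 1
    return OverlapMatrix(counts)


def nmi(p1, p2: Partition) -> float:
    """Normalized mutual information between two partitions (or groups vs a
    partition), from the overlap matrix.

    Degenerate cases follow the formula's limit: if either side is a single
    block the value is 0, unless both are, in which case 1.
    """
    ov = overlap_matrix(p1, p2) if not isinstance(p1, OverlapMatrix) else p1
    N = ov.counts.values.astype(float)
    n = N.sum()
    if n == 0:
        raise ValueError("empty overlap matrix")
    rows = N.sum(axis=1)
    cols = N.sum(axis=0)
    single_row = (rows > 0).sum() <= 1
    single_col = (cols > 0).sum() <= 1
    if single_row or single_col:
        return 1.0 if (single_row and single_col) else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = N * n / np.outer(rows, cols)
        terms = np.where(N > 0, N * np.log(np.where(N > 0, ratio, 1.0)), 0.0)
    num = -2.0 * terms.sum()
    den = (rows[rows > 0] * np.log(rows[rows > 0] / n)).sum() + (
        cols[cols > 0] * np.log(cols[cols > 0] / n)
    ).sum()
    return float(num / den)


def group_spectrum(group, p: Partition, label: str = "") -> GroupSpectrum:
    """Decompose one nonempty group over the partition's modules."""
    members = set(group)
    if not members:
        raise ValueError("group is empty")
    unknown = sorted(m for m in members if m not in p.assignment)
    if unknown:
        raise ValueError("group member(s) not in partition: " + ", ".join(unknown))
    module_labels = sorted(set(p.assignment.values()))
    counts = np.zeros(len(module_labels))
    index = {m: i for i, m in enumerate(module_labels)}
    for m in members:
        counts[index[p.assignment[m]]] += 1
    return GroupSpectrum(label=label, fractions=counts / counts.sum(), size=len(members))


def modular_distance(s1: GroupSpectrum, s2: GroupSpectrum) -> float:
    """Euclidean distance between two modular spectra."""
    if len(s1.fractions) != len(s2.fractions):
        raise ValueError("spectra have different lengths")
    return float(np.linalg.norm(s1.fractions - s2.fractions))


def module_summary(
    net: Connectome, p: Partition
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module-by-module link density matrix and neuron-type composition.

    Density entry (a, b) is the number of directed links from module a to
    module b divided by the number of ordered cross pairs (n_a * n_b, or
    n_a * (n_a - 1) on the diagonal).
    """
    modules = p.modules()
    labels = sorted(modules)
    g = net.graph
    dens = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in labels:
        for b in labels:
            na, nb = len(modules[a]), len(modules[b])
            possible = na * (na - 1) if a == b else na * nb
            if possible == 0:
                dens.loc[a, b] = np.nan
                continue
            links = sum(
                1 for u in modules[a] for v in g.successors(u) if v in modules[b] and v != u
            )
            dens.loc[a, b] = links / possible
    ntypes = sorted({nr.ntype for nr in net.neurons.values()})
    comp = pd.DataFrame(0, index=labels, columns=ntypes, dtype=int)
    for n, m in p.assignment.items():
        if n in net.neurons:
            comp.loc[m, net.neurons[n].ntype] += 1
    return dens, comp


# ---------------------------------------------------------------------------
# group distance matrices and dendrograms
# ---------------------------------------------------------------------------


@dataclass
class GroupDistances:
    """Pairwise group distances in modular and physical space."""

    modular: pd.DataFrame
    physical: pd.DataFrame
    modular_linkage: np.ndarray
    physical_linkage: np.ndarray
    labels: list[str]
    matrix_correlation: float
    tree_correlation: float

    def newick(self, which: str = "modular") -> str:
        z = self.modular_linkage if which == "modular" else self.physical_linkage
        return linkage_to_newick(z, self.labels)


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def dendrogram_path_lengths(linkage: np.ndarray, n_leaves: int) -> np.ndarray:
    """Leaf-pair path lengths (edge counts) in the binary merge tree."""
    tree = sch.to_tree(linkage)
    depth: dict[int, int] = {}
    leaves_below: dict[int, list[int]] = {}
    dist = np.zeros((n_leaves, n_leaves))

    def walk(node, d: int) -> list[int]:
        depth[node.id] = d
        if node.is_leaf():
            leaves_below[node.id] = [node.id]
            return [node.id]
        left = walk(node.left, d + 1)
        right = walk(node.right, d + 1)
        for a in left:
            for b in right:
                steps = (depth[a] - d) + (depth[b] - d)
                dist[a, b] = dist[b, a] = steps
        leaves_below[node.id] = left + right
        return leaves_below[node.id]

    walk(tree, 0)
    return dist


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = sch.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    if tree.is_leaf():
        return f"{labels[tree.id]};"
    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def group_distance_matrices(
    groups, p: Partition, positions: dict[str, float]
) -> GroupDistances:
    """Modular (spectrum) and physical (position) distance matrices between
    groups, their UPGMA dendrograms, and the two correlations.

    The physical distance between two groups is the mean |x_i - x_j| over
    all cross-group neuron pairs. ``matrix_correlation`` is the Pearson
    correlation of the off-diagonal entries of the two matrices;
    ``tree_correlation`` correlates leaf-pair path lengths (edge counts) of
    the two dendrograms.
    """
    groups = _as_groups(groups)
    labels = list(groups)
    if any(len(members) == 0 for members in groups.values()):
        raise ValueError("empty group")
    spectra = [group_spectrum(groups[g], p, label=g) for g in labels]
    k = len(labels)
    dmod = np.zeros((k, k))
    dphys = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dmod[i, j] = dmod[j, i] = modular_distance(spectra[i], spectra[j])
            xi = np.array([positions[n] for n in groups[labels[i]]])
            xj = np.array([positions[n] for n in groups[labels[j]]])
            dphys[i, j] = dphys[j, i] = float(
                np.abs(xi[:, None] - xj[None, :]).mean()
            )
    zm = sch.linkage(ssd.squareform(dmod, checks=False), method="average")
    zp = sch.linkage(ssd.squareform(dphys, checks=False), method="average")
    if k > 2 and np.std(_offdiag(dmod)) > 0 and np.std(_offdiag(dphys)) > 0:
        mat_corr = float(pearsonr(_offdiag(dmod), _offdiag(dphys))[0])
        pm = dendrogram_path_lengths(zm, k)
        pp = dendrogram_path_lengths(zp, k)
        if np.std(_offdiag(pm)) > 0 and np.std(_offdiag(pp)) > 0:
            tree_corr = float(pearsonr(_offdiag(pm), _offdiag(pp))[0])
        else:
            tree_corr = float("nan")
    else:
        mat_corr = tree_corr = float("nan")
    return GroupDistances(
        modular=pd.DataFrame(dmod, index=labels, columns=labels),
        physical=pd.DataFrame(dphys, index=labels, columns=labels),
        modular_linkage=zm,
        physical_linkage=zp,
        labels=labels,
        matrix_correlation=mat_corr,
        tree_correlation=tree_corr,
    )
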