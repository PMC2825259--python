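"""Cell-lineage trees and lineage distances between neurons.

Lineage distance between two cells counts cell divisions via the last
common progenitor: with n_a and n_b divisions from that progenitor down to
each cell, the distance is n_a + n_b - 1 (the initial division out of the
common progenitor is counted only once), 0 for a cell with itself, and
simply the number of divisions between them when one cell is an ancestor
of the other (only one branch exists, so there is no shared first division
to discount).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .modularity import Partition

__all__ = ["LineageTree", "lineage_distance", "module_lineage_matrix"]


@dataclass
class LineageTree:
    """A rooted division tree stored as a child -> parent map."""

    parents: dict[str, str]

    def __post_init__(self) -> None:
        self._depth: dict[str, int] = {}
        roots = {p for p in self.parents.values() if p not in self.parents}
        if not roots and self.parents:
            raise ValueError("tree has no root (cycle?)")
        self.roots = sorted(roots)
        # validate acyclicity by walking every chain
        for cell in self.parents:
            seen = {cell}
            cur = cell
            while cur in self.parents:
                cur = self.parents[cur]
                if cur in seen:
                    raise ValueError(f"cycle in lineage tree at {cur!r}")
                seen.add(cur)

    @property
    def cells(self) -> set[str]:
        return set(self.parents) | set(self.roots)

    def depth(self, cell: str) -> int:
        if cell not in self._depth:
            d = 0
            cur = cell
            while cur in self.parents:
                cur = self.parents[cur]
                d += 1
            self._depth[cell] = d
        return self._depth[cell]

    def ancestors(self, cell: str) -> list[str]:
        """Cell itself followed by its ancestor chain up to the root."""
        chain = [cell]
        cur = cell
        while cur in self.parents:
            cur = self.parents[cur]
            chain.append(cur)
        return chain

    @classmethod
    def from_parent_csv(cls, path: str | Path) -> "LineageTree":
        """Two-column ``child,parent`` CSV (header required)."""
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 2:
            raise ValueError("expected two columns: child, parent")
        child_col, parent_col = df.columns[:2]
        return cls({str(r[child_col]): str(r[parent_col]) for _, r in df.iterrows()})

    @classmethod
    def from_newick(cls, newick: str) -> "LineageTree":
        """Parse a Newick string; unnamed internal nodes are auto-named."""
        import io as _io
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        parents: dict[str, str] = {}
        counter = [0]

        def name_of(node) -> str:
            if node.taxon is not None and node.taxon.label:
                return node.taxon.label
            if node.label:
                return node.label
            counter[0] += 1
            node.label = f"_internal{counter[0]}"
            return node.label

        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                parents[name_of(node)] = name_of(node.parent_node)
        return cls(parents)

    def to_parent_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            sorted(self.parents.items()), columns=["child", "parent"]
        ).to_csv(path, index=False)
        return path


def lineage_distance(tree: LineageTree, a: str, b: str) -> int:
    """Division-count distance between two cells (see module docstring)."""
    cells = tree.cells
    for c in (a, b):
        if c not in cells:
            raise KeyError(f"cell {c!r} not in lineage tree")
    if a == b:
        return 0
    anc_a = tree.ancestors(a)
    set_a = {c: i for i, c in enumerate(anc_a)}
    n_b = 0
    cur = b
    while cur not in set_a:
        if cur not in tree.parents:
            raise ValueError(f"cells {a!r} and {b!r} share no common progenitor")
        cur = tree.parents[cur]
        n_b += 1
    n_a = set_a[cur]
    if n_a == 0 or n_b == 0:  # ancestor-descendant pair
        return n_a + n_b
    return n_a + n_b - 1


def module_lineage_matrix(
    tree_or_matrix, p: Partition
) -> pd.DataFrame:
    """M x M mean pairwise lineage distance within and between modules.

    Accepts either a :class:`LineageTree` or a precomputed pairwise
    distance DataFrame (nodes x nodes), in which case tree operations are
    bypassed. Diagonal entries for singleton modules are NaN.
    """
    modules = p.modules()
    labels = sorted(modules)
    if isinstance(tree_or_matrix, LineageTree):
        tree = tree_or_matrix
        missing = sorted(n for n in p.assignment if n not in tree.cells)
        if missing:
            raise ValueError("node(s) missing from tree: " + ", ".join(missing[:5]))
        dist = lambda x, y: lineage_distance(tree, x, y)  # noqa: E731
    else:
        dmat = tree_or_matrix
        dist = lambda x, y: float(dmat.loc[x, y])  # noqa: E731

    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i:]:
            if a == b:
                members = sorted(modules[a])
                vals = [
                    dist(x, y)
                    for xi, x in enumerate(members)
                    for y in members[xi + 1 :]
                ]
            else:
                vals = [dist(x, y) for x in modules[a] for y in modules[b]]
            if vals:
                out.loc[a, b] = out.loc[b, a] = float(np.mean(vals))
    return out
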