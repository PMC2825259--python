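"""Reading and writing connectome tables and derived graph objects.

The input dialect is the revised *C. elegans* wiring tables: a connection
table with columns ``Neuron1, Neuron2, Type, Nbr`` where ``Type`` is one of
the codes ``S`` (chemical send), ``Sp`` (send, polyadic), ``R`` (receive),
``Rp`` (receive, polyadic), ``EJ`` (electrical / gap junction) or ``NMJ``
(neuromuscular junction), and a neuron metadata table with columns
``Neuron, Position, Ganglion, NType`` and optionally ``Lineage``.

Three network views can be built from one record set: the gap-junction
network (undirected), the synaptic network (directed) and the combined
network whose link weights are the total number of synaptic plus gap
junctional contacts from one neuron to another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "Neuron",
    "ConnectionRecord",
    "Connectome",
    "read_tables",
    "build_network",
    "write_graphml",
    "read_graphml",
    "write_edgelist",
    "write_partition_csv",
    "CTYPE_CODES",
]

#: wormatlas ``Type`` codes -> canonical connection types
CTYPE_CODES: dict[str, str] = {
    "S": "chemical_send",
    "Sp": "chemical_send_poly",
    "R": "chemical_receive",
    "Rp": "chemical_receive_poly",
    "EJ": "electrical",
    "NMJ": "neuromuscular",
}

_CANONICAL_CTYPES = frozenset(CTYPE_CODES.values())

_SEND = ("chemical_send", "chemical_send_poly")
_RECV = ("chemical_receive", "chemical_receive_poly")


@dataclass(frozen=True)
class Neuron:
    """A neuron with its cell-body position along the longitudinal axis.

    ``position`` is a fraction of body length (dimensionless, typically in
    [0, 1]); only the longitudinal coordinate is kept.
    """

    name: str
    position: float
    ganglion: str
    ntype: str
    lineage_name: str | None = None


@dataclass(frozen=True)
class ConnectionRecord:
    """One row of the connection table: ``pre -> post`` with multiplicity."""

    pre: str
    post: str
    ctype: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.ctype not in _CANONICAL_CTYPES:
            raise ValueError(f"unknown connection type {self.ctype!r}")


class Connectome:
    """A directed weighted view of the neuronal network.

    Holds the two connection channels separately — ``gap`` (an undirected
    :class:`networkx.Graph`, every junction mirrored in the directed view)
    and ``syn`` (a directed :class:`networkx.DiGraph`) — plus the combined
    directed graph exposed as :attr:`graph`. Edge weights are connection
    multiplicities, or 1 everywhere when ``weighted`` is False.
    """

    def __init__(
        self,
        neurons: Mapping[str, Neuron],
        gap: nx.Graph,
        syn: nx.DiGraph,
        mode: str,
        weighted: bool,
    ) -> None:
        self.neurons = dict(neurons)
        self.gap = gap
        self.syn = syn
        self.mode = mode
        self.weighted = weighted
        self._graph: nx.DiGraph | None = None

    # -- combined directed view -------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        """Combined directed graph: gap edges mirrored, weights summed."""
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.neurons)
            for u, v, w in self.syn.edges(data="weight"):
                g.add_edge(u, v, weight=float(w))
            for u, v, w in self.gap.edges(data="weight"):
                for a, b in ((u, v), (v, u)):
                    if g.has_edge(a, b):
                        g[a][b]["weight"] += float(w)
                    else:
                        g.add_edge(a, b, weight=float(w))
            self._graph = g
        return self._graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.neurons)

    @property
    def n_nodes(self) -> int:
        return len(self.neurons)

    @property
    def L(self) -> int:
        """Number of directed links (gap junctions count once per direction)."""
        return self.graph.number_of_edges()

    @property
    def W(self) -> float:
        """Total weight over all directed links."""
        return float(self.graph.size(weight="weight"))

    def degree(self, node: str) -> int:
        return self.graph.in_degree(node) + self.graph.out_degree(node)

    def strength_in(self, node: str) -> float:
        return float(self.graph.in_degree(node, weight="weight"))

    def strength_out(self, node: str) -> float:
        return float(self.graph.out_degree(node, weight="weight"))

    @property
    def isolated(self) -> set[str]:
        """Nodes with no edge in the current view (retained but flagged)."""
        g = self.graph
        return {n for n in g if g.in_degree(n) == 0 and g.out_degree(n) == 0}

    def positions(self) -> dict[str, float]:
        return {n: nr.position for n, nr in self.neurons.items()}

    def ganglia(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for n, nr in self.neurons.items():
            out.setdefault(nr.ganglion, set()).add(n)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Connectome(mode={self.mode!r}, weighted={self.weighted}, "
            f"n={self.n_nodes}, L={self.L}, W={self.W:g})"
        )


# ---------------------------------------------------------------------------
# table reading
# ---------------------------------------------------------------------------

_NEURON_COLS = ("Neuron", "Position", "Ganglion", "NType")
_CONN_COLS = ("Neuron1", "Neuron2", "Type", "Nbr")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_tables(
    neuron_path: str | Path, connection_path: str | Path
) -> tuple[list[Neuron], list[ConnectionRecord]]:
    """Parse the neuron metadata and connection tables.

    Unknown connection-type codes are collected and reported through a
    single warning (the rows are not silently dropped without notice).
    A connection row naming a neuron absent from the metadata table is a
    hard error listing every offender.
    """
    ndf = _read_delimited(neuron_path)
    missing = [c for c in _NEURON_COLS if c not in ndf.columns]
    if missing:
        raise ValueError(f"neuron table missing column(s): {', '.join(missing)}")
    has_lineage = "Lineage" in ndf.columns

    neurons: list[Neuron] = []
    seen: set[str] = set()
    for row in ndf.itertuples(index=False):
        name = str(getattr(row, "Neuron"))
        if name in seen:
            raise ValueError(f"duplicate neuron name {name!r} in neuron table")
        seen.add(name)
        lineage = str(getattr(row, "Lineage")) if has_lineage else None
        neurons.append(
            Neuron(
                name=name,
                position=float(getattr(row, "Position")),
                ganglion=str(getattr(row, "Ganglion")),
                ntype=str(getattr(row, "NType")),
                lineage_name=lineage,
            )
        )

    cdf = _read_delimited(connection_path)
    missing = [c for c in _CONN_COLS if c not in cdf.columns]
    if missing:
        raise ValueError(f"connection table missing column(s): {', '.join(missing)}")

    records: list[ConnectionRecord] = []
    unknown_codes: set[str] = set()
    referenced: set[str] = set()
    for row in cdf.itertuples(index=False):
        code = str(getattr(row, "Type"))
        ctype = CTYPE_CODES.get(code, code if code in _CANONICAL_CTYPES else None)
        pre, post = str(getattr(row, "Neuron1")), str(getattr(row, "Neuron2"))
        if ctype is None:
            unknown_codes.add(code)
            continue
        # NMJ rows name a muscle in Neuron2; only neuron endpoints are checked
        referenced.add(pre)
        if ctype != "neuromuscular":
            referenced.add(post)
        records.append(
            ConnectionRecord(pre=pre, post=post, ctype=ctype, count=int(getattr(row, "Nbr")))
        )

    if unknown_codes:
        warnings.warn(
            "unknown connection-type code(s) skipped: "
            + ", ".join(sorted(unknown_codes)),
            stacklevel=2,
        )
    unmatched = sorted(referenced - seen)
    if unmatched:
        raise ValueError(
            "connection table references neuron(s) absent from the neuron "
            "table: " + ", ".join(unmatched)
        )
    return neurons, records


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def _chemical_edges(records: Iterable[ConnectionRecord]) -> dict[tuple[str, str], int]:
    """Directed chemical edges with reciprocal receive records resolved.

    The wiring table lists each chemical synapse from both sides: a receive
    record ``(a, b, R)`` is the mirror of a send record ``(b, a, S)``.
    Receive records whose mirror send exists are dropped; an unmatched
    receive record is reversed into a send edge.
    """
    sends: dict[tuple[str, str], int] = {}
    recvs: dict[tuple[str, str], int] = {}
    for r in records:
        if r.ctype in _SEND:
            key = (r.pre, r.post)
            sends[key] = sends.get(key, 0) + r.count
        elif r.ctype in _RECV:
            key = (r.post, r.pre)  # reversed: post is the true sender
            recvs[key] = recvs.get(key, 0) + r.count
    for key, cnt in recvs.items():
        if key not in sends:
            sends[key] = cnt
    return sends


def _gap_edges(records: Iterable[ConnectionRecord]) -> dict[tuple[str, str], int]:
    """Undirected gap-junction weights per unordered pair.

    The table conventionally lists each junction from both sides with equal
    multiplicity; the two orientation sums are collapsed by taking their
    maximum (warning when they disagree), so a single one-sided record and
    the two-sided convention yield the same weight.
    """
    by_dir: dict[tuple[str, str], int] = {}
    for r in records:
        if r.ctype == "electrical":
            key = (r.pre, r.post)
            by_dir[key] = by_dir.get(key, 0) + r.count
    out: dict[tuple[str, str], int] = {}
    for (a, b), w in by_dir.items():
        key = (min(a, b), max(a, b))
        if key in out and out[key] != w:
            warnings.warn(
                f"gap-junction multiplicities disagree across orientations "
                f"for pair {key}: {out[key]} vs {w}; keeping the larger",
                stacklevel=3,
            )
        out[key] = max(out.get(key, 0), w)
    return out


def build_network(
    neurons: Iterable[Neuron],
    records: Iterable[ConnectionRecord],
    mode: str = "combined",
    weighted: bool = True,
) -> Connectome:
    """Assemble a :class:`Connectome` in one of three modes.

    ``gap`` keeps only electrical junctions (symmetric); ``syn`` keeps only
    chemical send edges (directed); ``combined`` sums both channels per
    ordered pair. Neuromuscular records are excluded everywhere, as are
    self-loops. ``weighted=False`` binarizes every channel weight to 1.
    """
    if mode not in ("gap", "syn", "combined"):
        raise ValueError(f"unknown mode {mode!r}; expected gap, syn or combined")
    nmap = {n.name: n for n in neurons}
    records = list(records)

    gap = nx.Graph()
    syn = nx.DiGraph()
    gap.add_nodes_from(nmap)
    syn.add_nodes_from(nmap)

    if mode in ("gap", "combined"):
        for (a, b), w in _gap_edges(records).items():
            if a == b:
                continue
            gap.add_edge(a, b, weight=(float(w) if weighted else 1.0))
    if mode in ("syn", "combined"):
        for (a, b), w in _chemical_edges(records).items():
            if a == b:
                continue
            syn.add_edge(a, b, weight=(float(w) if weighted else 1.0))
    return Connectome(nmap, gap, syn, mode=mode, weighted=weighted)


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------


def write_graphml(net: Connectome, path: str | Path) -> Path:
    """Export the combined directed graph with per-channel weights."""
    g = nx.DiGraph()
    for n, nr in net.neurons.items():
        g.add_node(
            n,
            position=nr.position,
            ganglion=nr.ganglion,
            ntype=nr.ntype,
            lineage=nr.lineage_name or "",
        )
    for u, v, w in net.syn.edges(data="weight"):
        g.add_edge(u, v, syn_weight=float(w), gap_weight=0.0)
    for u, v, w in net.gap.edges(data="weight"):
        for a, b in ((u, v), (v, u)):
            if g.has_edge(a, b):
                g[a][b]["gap_weight"] = float(w)
            else:
                g.add_edge(a, b, syn_weight=0.0, gap_weight=float(w))
    g.graph["mode"] = net.mode
    g.graph["weighted"] = net.weighted
    path = Path(path)
    nx.write_graphml(g, path)
    return path


def read_graphml(path: str | Path) -> Connectome:
    """Re-read a GraphML file written by :func:`write_graphml`."""
    g = nx.read_graphml(path)
    neurons = {
        n: Neuron(
            name=n,
            position=float(d.get("position", 0.0)),
            ganglion=str(d.get("ganglion", "")),
            ntype=str(d.get("ntype", "")),
            lineage_name=(str(d["lineage"]) or None) if "lineage" in d else None,
        )
        for n, d in g.nodes(data=True)
    }
    gap = nx.Graph()
    syn = nx.DiGraph()
    gap.add_nodes_from(neurons)
    syn.add_nodes_from(neurons)
    for u, v, d in g.edges(data=True):
        sw = float(d.get("syn_weight", 0.0))
        gw = float(d.get("gap_weight", 0.0))
        if sw > 0:
            syn.add_edge(u, v, weight=sw)
        if gw > 0:
            gap.add_edge(u, v, weight=gw)
    mode = str(g.graph.get("mode", "combined"))
    weighted = bool(g.graph.get("weighted", True))
    return Connectome(neurons, gap, syn, mode=mode, weighted=weighted)


def write_edgelist(net: Connectome, path: str | Path) -> Path:
    """Plain TSV edge list of the combined directed view."""
    path = Path(path)
    rows = [
        {"pre": u, "post": v, "weight": w}
        for u, v, w in sorted(net.graph.edges(data="weight"))
    ]
    pd.DataFrame(rows, columns=["pre", "post", "weight"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_partition_csv(partition, path: str | Path) -> Path:
    """CSV with columns ``node, module`` in sorted node order."""
    path = Path(path)
    rows = [{"node": n, "module": m} for n, m in sorted(partition.assignment.items())]
    pd.DataFrame(rows, columns=["node", "module"]).to_csv(path, index=False)
    return path
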