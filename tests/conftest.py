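"""Shared fixtures: toy network builders and a synthetic bundle."""

from __future__ import annotations

import pytest

from mesoconn import (
    ConnectionRecord,
    Neuron,
    SynthParams,
    build_network,
    generate_connectome,
    read_tables,
)


def make_net(
    directed_edges=(),
    undirected_edges=(),
    extra_nodes=(),
    weighted=True,
    mode="combined",
    positions=None,
    ganglia=None,
):
    """Build a Connectome from explicit edge lists.

    ``directed_edges`` are (pre, post, weight) chemical synapses;
    ``undirected_edges`` are (a, b, weight) gap junctions.
    """
    names = set(extra_nodes)
    for e in directed_edges:
        names.update(e[:2])
    for e in undirected_edges:
        names.update(e[:2])
    positions = positions or {}
    ganglia = ganglia or {}
    neurons = [
        Neuron(
            name=n,
            position=positions.get(n, i / max(len(names), 1)),
            ganglion=ganglia.get(n, "G1"),
            ntype="interneuron",
        )
        for i, n in enumerate(sorted(names))
    ]
    records = [
        ConnectionRecord(pre=a, post=b, ctype="chemical_send", count=int(w))
        for a, b, w in directed_edges
    ] + [
        ConnectionRecord(pre=a, post=b, ctype="electrical", count=int(w))
        for a, b, w in undirected_edges
    ]
    return build_network(neurons, records, mode=mode, weighted=weighted)


@pytest.fixture(scope="session")
def synth_bundle(tmp_path_factory):
    """A 60-node, 3-module synthetic connectome written to disk and read
    back through the I/O layer, with its planted partition."""
    outdir = tmp_path_factory.mktemp("synth")
    params = SynthParams(n=60, M=3, seed=1)
    _, _, planted, paths = generate_connectome(params, outdir=outdir)
    neurons, records = read_tables(paths["neurons"], paths["connections"])
    net = build_network(neurons, records, mode="combined", weighted=True)
    return {"net": net, "planted": planted, "params": params, "paths": paths}


@pytest.fixture
def triangles():
    """Two disjoint undirected triangles (classic Q = 0.5 example)."""
    return make_net(
        undirected_edges=[
            ("a", "b", 1),
            ("b", "c", 1),
            ("a", "c", 1),
            ("d", "e", 1),
            ("e", "f", 1),
            ("d", "f", 1),
        ]
    )
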