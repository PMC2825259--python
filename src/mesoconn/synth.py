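"""Synthetic connectome generator with planted modular structure.

Emits neuron and connection tables in exactly the dialect that
:mod:`mesoconn.io` reads, so the whole pipeline can be exercised without
any real dataset. The generated network is a directed planted-partition
graph: links fall with probability ``p_in`` inside modules and ``p_out``
between them; multiplicities are geometric (mimicking the exponentially
decaying strength distributions of real connectomes rather than heavy
tails); a fraction of links become symmetric gap junctions; cell-body
positions cluster per module on the unit interval; "ganglion" labels agree
with the planted module up to a noise probability; and an optional binary
lineage tree can be planted with module-aligned clades.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lineage import LineageTree
from .modularity import Partition

__all__ = ["SynthParams", "generate_connectome", "generate_lineage"]

NTYPES = ("sensory", "motor", "interneuron", "polymodal")
NTYPE_PROBS = (0.3, 0.35, 0.3, 0.05)


@dataclass(frozen=True)
class SynthParams:
    """Generator settings; defaults give a clearly modular mid-size network."""

    n: int = 120
    M: int = 4
    p_in: float = 0.5
    p_out: float = 0.02
    weight_mean: float = 2.0
    gap_fraction: float = 0.25
    spatial_spread: float = 0.06
    ganglion_noise: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n >= self.M >= 1):
            raise ValueError("need n >= M >= 1")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not (0.0 <= self.gap_fraction <= 1.0):
            raise ValueError("gap_fraction must be in [0, 1]")
        if self.weight_mean < 1.0:
            raise ValueError("weight_mean must be >= 1 (geometric multiplicity)")
        if self.spatial_spread < 0 or not (0 <= self.ganglion_noise <= 1):
            raise ValueError("invalid spatial_spread or ganglion_noise")


def _neuron_name(i: int) -> str:
    return f"N{i:03d}"


def generate_connectome(
    params: SynthParams, outdir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, Partition, dict[str, Path]]:
    """Generate (neuron table, connection table, planted partition).

    When ``outdir`` is given, the two tables are written there as
    ``neurons.tsv`` and ``connections.tsv`` (wormatlas dialect) together
    with a ``synth_params.yaml`` record of the settings; the returned dict
    maps logical names to the written paths (empty otherwise).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n, M = params.n, params.M
    names = [_neuron_name(i) for i in range(n)]
    modules = np.array([i % M for i in range(n)])
    planted = Partition({names[i]: int(modules[i]) for i in range(n)})

    # --- links ----------------------------------------------------------
    # Channel is decided per unordered pair; a gap pair uses a single
    # Bernoulli draw and is mirrored by construction, so the marginal
    # density of every ordered pair is exactly p_in / p_out either way.
    p_mat = np.where(
        modules[:, None] == modules[None, :], params.p_in, params.p_out
    )
    np.fill_diagonal(p_mat, 0.0)
    adj = rng.random((n, n)) < p_mat
    weights = rng.geometric(1.0 / params.weight_mean, size=(n, n))
    gap_pair = rng.random((n, n)) < params.gap_fraction

    conn_rows = []
    for i in range(n):
        for j in range(n):
            if i < j and gap_pair[i, j]:
                if adj[i, j]:
                    conn_rows.append(
                        {
                            "Neuron1": names[i],
                            "Neuron2": names[j],
                            "Type": "EJ",
                            "Nbr": int(weights[i, j]),
                        }
                    )
            elif i != j and not gap_pair[min(i, j), max(i, j)] and adj[i, j]:
                conn_rows.append(
                    {
                        "Neuron1": names[i],
                        "Neuron2": names[j],
                        "Type": "S",
                        "Nbr": int(weights[i, j]),
                    }
                )
    conn_df = pd.DataFrame(conn_rows, columns=["Neuron1", "Neuron2", "Type", "Nbr"])

    # --- metadata -------------------------------------------------------
    centers = (modules + 0.5) / M
    positions = np.clip(
        rng.normal(centers, params.spatial_spread), 0.0, 1.0
    )
    noisy = rng.random(n) < params.ganglion_noise
    ganglia = []
    for i in range(n):
        g = modules[i]
        if noisy[i] and M > 1:
            others = [m for m in range(M) if m != g]
            g = others[rng.integers(len(others))]
        ganglia.append(f"G{g + 1}")
    ntypes = rng.choice(NTYPES, size=n, p=NTYPE_PROBS)
    neuron_df = pd.DataFrame(
        {
            "Neuron": names,
            "Position": np.round(positions, 6),
            "Ganglion": ganglia,
            "NType": ntypes,
            "Lineage": names,  # leaves of a generated lineage tree reuse names
        }
    )

    paths: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths["neurons"] = outdir / "neurons.tsv"
        paths["connections"] = outdir / "connections.tsv"
        paths["params"] = outdir / "synth_params.yaml"
        neuron_df.to_csv(paths["neurons"], sep="\t", index=False)
        conn_df.to_csv(paths["connections"], sep="\t", index=False)
        paths["params"].write_text(yaml.safe_dump(asdict(params)))
    return neuron_df, conn_df, planted, paths


def _random_binary(leaves: list[str], rng: np.random.Generator, counter: list[int]) -> tuple[str, dict[str, str]]:
    """Random binary tree over ``leaves`` by iterative pairwise merging."""
    parents: dict[str, str] = {}
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        counter[0] += 1
        new = f"P{counter[0]:03d}"
        parents[nodes[i]] = new
        parents[nodes[j]] = new
        nodes[i] = new
        del nodes[j]
    return nodes[0], parents


def generate_lineage(
    n: int,
    seed: int = 0,
    modules: dict[str, int] | Partition | None = None,
) -> LineageTree:
    """Random binary division tree with ``n`` leaves named like neurons.

    With ``modules`` given (a planted partition), each module's members
    form a clade, planting a lineage-module correlation: within-module
    lineage distances are then systematically smaller than between-module
    ones. Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    leaves = [_neuron_name(i) for i in range(n)]
    counter = [0]
    if modules is None:
        root, parents = _random_binary(leaves, rng, counter)
        return LineageTree(parents)
    assignment = modules.assignment if isinstance(modules, Partition) else dict(modules)
    groups: dict[int, list[str]] = {}
    for leaf in leaves:
        groups.setdefault(assignment[leaf], []).append(leaf)
    parents: dict[str, str] = {}
    clade_roots = []
    for m in sorted(groups):
        root_m, par_m = _random_binary(groups[m], rng, counter)
        parents.update(par_m)
        clade_roots.append(root_m)
    if len(clade_roots) > 1:
        _, par_top = _random_binary(clade_roots, rng, counter)
        parents.update(par_top)
    return LineageTree(parents)
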