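"""Intra/inter-module role cartography of individual neurons.

Each node is placed in a z-P plane: the within-module degree z-score

.. math:: z_i = (\\kappa_i - \\bar{\\kappa}_{c_i}) / \\sigma_{\\kappa_{c_i}}

standardizes the number of links a node has to other members of its own
module, and the participation coefficient

.. math:: P_i = 1 - \\sum_{s=1}^{M} (\\kappa_{is}/k_i)^2

measures how evenly its links spread over all modules (0 when every link is
internal, approaching 1 when uniformly distributed). Thresholds on (z, P)
classify nodes into seven roles: non-hubs R1 (ultra-peripheral), R2
(peripheral), R3 (satellite connector), R4 (kinless), and hubs R5
(provincial), R6 (connector), R7 (global). Degrees here are unweighted
totals (in + out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Connectome
from .modularity import Partition
from .randomize import constrained_rewire

__all__ = ["RoleThresholds", "cartography", "assign_roles", "role_to_role", "ROLES"]

ROLES = ("R1", "R2", "R3", "R4", "R5", "R6", "R7")


@dataclass(frozen=True)
class RoleThresholds:
    """Cutoffs in the z-P plane (the standard cartographic scheme)."""

    z_hub: float = 2.5
    nonhub_p: tuple[float, float, float] = (0.05, 0.62, 0.80)  # R1|R2|R3|R4
    hub_p: tuple[float, float] = (0.30, 0.75)  # R5|R6|R7

    def role(self, z: float, p: float) -> str:
        if z < self.z_hub:
            cuts = self.nonhub_p
            if p < cuts[0]:
                return "R1"
            if p < cuts[1]:
                return "R2"
            if p < cuts[2]:
                return "R3"
            return "R4"
        cuts = self.hub_p
        if p < cuts[0]:
            return "R5"
        if p < cuts[1]:
            return "R6"
        return "R7"


def _module_link_counts(net: Connectome, p: Partition) -> pd.DataFrame:
    """Per node, number of (in + out) links to each module."""
    g = net.graph
    modules = sorted(set(p.assignment.values()))
    counts = pd.DataFrame(0, index=net.nodes, columns=modules, dtype=int)
    for u, v in g.edges():
        counts.loc[u, p.assignment[v]] += 1
        counts.loc[v, p.assignment[u]] += 1
    return counts


def cartography(
    net: Connectome, p: Partition, thresholds: RoleThresholds | None = None
) -> pd.DataFrame:
    """Per-node cartography table: module, kappa, z, P and role.

    kappa is the node's link count to its own module; z standardizes kappa
    within each module (modules with zero kappa variance get z = 0 for all
    members); P uses the node's link counts to every module. Isolated
    nodes get z = 0, P = 0 and are flagged.
    """
    missing = [n for n in net.neurons if n not in p.assignment]
    if missing:
        raise ValueError("partition missing node(s): " + ", ".join(missing[:5]))
    counts = _module_link_counts(net, p)
    nodes = net.nodes
    own = np.array([p.assignment[n] for n in nodes])
    kappa = np.array([counts.loc[n, p.assignment[n]] for n in nodes], dtype=float)
    k = counts.sum(axis=1).to_numpy(dtype=float)

    z = np.zeros(len(nodes))
    for m in np.unique(own):
        sel = own == m
        sd = kappa[sel].std()
        if sd > 0:
            z[sel] = (kappa[sel] - kappa[sel].mean()) / sd

    with np.errstate(divide="ignore", invalid="ignore"):
        frac2 = (counts.to_numpy(dtype=float) / np.where(k > 0, k, 1)[:, None]) ** 2
    part = np.where(k > 0, 1.0 - frac2.sum(axis=1), 0.0)
    # clip tiny negative rounding noise
    part = np.clip(part, 0.0, 1.0)

    df = pd.DataFrame(
        {
            "node": nodes,
            "module": own,
            "kappa": kappa.astype(int),
            "k": k.astype(int),
            "z": z,
            "P": part,
            "isolated": k == 0,
        }
    ).set_index("node")
    return assign_roles(df, thresholds)


def assign_roles(
    records: pd.DataFrame, thresholds: RoleThresholds | None = None
) -> pd.DataFrame:
    """Add/overwrite the ``role`` column from the (z, P) columns."""
    th = thresholds or RoleThresholds()
    records = records.copy()
    records["role"] = [th.role(z, p) for z, p in zip(records["z"], records["P"])]
    return records


def _role_link_counts(net: Connectome, roles: pd.Series) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=list(ROLES), columns=list(ROLES), dtype=int)
    for u, v in net.graph.edges():
        counts.loc[roles[u], roles[v]] += 1
    return counts


def role_to_role(
    net: Connectome,
    p: Partition,
    records: pd.DataFrame,
    n_replicates: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """7x7 z-score matrix of link abundance between role pairs.

    Empirical directed link counts between each ordered role pair are
    compared against a degree- and modularity-preserving randomized
    ensemble. Roles stay fixed at their empirical assignment; only link
    counts are recomputed per replicate. Rows/columns of roles absent from
    the empirical network are NaN, as are pairs with zero ensemble
    variance and matching counts reported as 0.
    """
    roles = records["role"]
    emp = _role_link_counts(net, roles)
    reps = np.zeros((n_replicates, len(ROLES), len(ROLES)))
    for i in range(n_replicates):
        rep = constrained_rewire(net, p, seed=int(seed) + i)
        reps[i] = _role_link_counts(rep, roles).to_numpy()
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        zmat = np.where(sd > 0, (emp.to_numpy() - mean) / np.where(sd > 0, sd, 1), 0.0)
    present = set(roles.unique())
    out = pd.DataFrame(zmat, index=list(ROLES), columns=list(ROLES))
    for r in ROLES:
        if r not in present:
            out.loc[r, :] = np.nan
            out.loc[:, r] = np.nan
    return out
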