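"""Wiring-cost models and the cost-versus-efficiency trade-off frontier.

Two cost models, both in body-length units along the longitudinal axis:

* dedicated-wire (DW): each connected pair of neurons is assumed to use its
  own wire, so cost sums |x_i - x_j| over all distinct connected unordered
  pairs (multiplicity does not multiply cost);
* common-wire (CW): each neuron runs a single process reaching its farthest
  connected partner, so cost sums, per neuron, the distance to its farthest
  neighbor (0 for isolated neurons).

The frontier is traced by rewiring the network with degrees fixed and
positions held invariant: each replicate realizes one (cost, efficiency)
point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Connectome
from .randomize import degree_preserving_rewire
from .stats import efficiency

__all__ = ["CostPoint", "wiring_cost", "tradeoff_curve", "bin_frontier"]

COST_MODELS = ("DW", "CW")


@dataclass
class CostPoint:
    """One (wiring cost, efficiency) observation."""

    cost: float
    efficiency: float
    model: str  # DW or CW
    source: str  # empirical or randomized
    seed: int | None = None


def wiring_cost(
    net: Connectome, positions: dict[str, float] | None = None, model: str = "DW"
) -> float:
    """Total wiring cost of the network under the DW or CW model."""
    if model not in COST_MODELS:
        raise ValueError(f"unknown cost model {model!r}; expected DW or CW")
    if positions is None:
        positions = net.positions()
    g = net.graph
    connected = [n for n in g if g.in_degree(n) + g.out_degree(n) > 0]
    missing = sorted(n for n in connected if n not in positions)
    if missing:
        raise ValueError("no position for neuron(s): " + ", ".join(missing[:5]))
    if model == "DW":
        pairs = {tuple(sorted((u, v))) for u, v in g.edges()}
        return float(sum(abs(positions[a] - positions[b]) for a, b in pairs))
    total = 0.0
    for n in connected:
        nbrs = (set(g.successors(n)) | set(g.predecessors(n))) - {n}
        if nbrs:
            total += max(abs(positions[n] - positions[m]) for m in nbrs)
    return float(total)


def tradeoff_curve(
    net: Connectome,
    positions: dict[str, float] | None = None,
    n_replicates: int = 20,
    seed: int = 0,
    models: tuple[str, ...] = COST_MODELS,
) -> list[CostPoint]:
    """Cost-efficiency points for the empirical network and a
    degree-preserving randomized ensemble (positions held fixed).

    Returns one empirical point per cost model plus one randomized point
    per replicate per model. Deterministic for a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if positions is None:
        positions = net.positions()
    points: list[CostPoint] = []
    e_emp = efficiency(net)
    for model in models:
        points.append(
            CostPoint(
                cost=wiring_cost(net, positions, model),
                efficiency=e_emp,
                model=model,
                source="empirical",
            )
        )
    for i in range(n_replicates):
        rep_seed = int(seed) + i
        rep = degree_preserving_rewire(net, seed=rep_seed)
        e_rep = efficiency(rep)
        for model in models:
            points.append(
                CostPoint(
                    cost=wiring_cost(rep, positions, model),
                    efficiency=e_rep,
                    model=model,
                    source="randomized",
                    seed=rep_seed,
                )
            )
    return points


def bin_frontier(points: list[CostPoint], n_bins: int = 20) -> pd.DataFrame:
    """Bin randomized points by cost; mean and sd of efficiency per bin.

    Presentation helper for the frontier plot; empirical points pass
    through untouched.
    """
    rows = []
    df = pd.DataFrame(
        [
            {"cost": p.cost, "efficiency": p.efficiency, "model": p.model}
            for p in points
            if p.source == "randomized"
        ]
    )
    for model, sub in df.groupby("model"):
        lo, hi = sub["cost"].min(), sub["cost"].max()
        edges = np.linspace(lo, hi, n_bins + 1) if hi > lo else np.array([lo, lo + 1])
        idx = np.clip(np.digitize(sub["cost"], edges) - 1, 0, len(edges) - 2)
        for b in np.unique(idx):
            sel = sub[idx == b]
            rows.append(
                {
                    "model": model,
                    "cost_mid": (edges[b] + edges[b + 1]) / 2,
                    "eff_mean": sel["efficiency"].mean(),
                    "eff_sd": sel["efficiency"].std(ddof=0),
                    "n": len(sel),
                }
            )
    return pd.DataFrame(rows, columns=["model", "cost_mid", "eff_mean", "eff_sd", "n"])
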