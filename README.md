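# mesoconn

Mesoscopic analysis of neuronal connectomes, built around the somatic
nervous system of *Caenorhabditis elegans*: 282 neurons whose chemical
synapses and gap junctions are completely mapped. The package asks how
that network is organized between the single-neuron and whole-animal
scales — what its modules are, whether they follow anatomy, development or
wiring economy, and which neurons knit the modules together.

## What it computes

- **Module detection.** Modularity of a partition {c_i} of a directed,
  weighted network,

  Q = (1/W) Σ_ij [ w_ij − s_i^out s_j^in / W ] δ(c_i, c_j),

  which reduces to the familiar Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j)
  for undirected unweighted graphs. The optimal partition is found by
  recursive spectral bisection of the modularity matrix
  B_ij = w_ij − s_i^out s_j^in / W (leading eigenvector of B + Bᵀ, split by
  sign), with greedy single-node refinement at each split and a final
  node-move pass over the whole partition.
- **Partition comparison.** Overlap (contingency) matrices, normalized
  mutual information, and *modular spectra*: each neuron group (ganglion,
  functional circuit) becomes a fraction vector over the modules, and
  Euclidean distances between spectra place groups in an abstract
  "modular space" with UPGMA dendrograms for both modular and physical
  distances.
- **Global structure.** Bow-tie (SCC/IN/OUT) decomposition, betweenness
  centrality, communication efficiency E = ⟨1/d_ij⟩ (finite on
  disconnected graphs), assortativity, neighbor-degree curves and
  degree/strength distributions.
- **Wiring economy.** Dedicated-wire (sum of |x_i − x_j| over connected
  pairs) and common-wire (per-neuron farthest neighbor) cost models, and
  the cost-efficiency frontier traced by degree-preserving rewiring with
  neuron positions held fixed.
- **Role cartography.** Within-module degree z-score and participation
  coefficient P per neuron, classification into roles R1–R7 (peripheral
  nodes through connector hubs), and role-to-role link z-scores against a
  degree- and modularity-preserving null ensemble.
- **Lineage.** Cell-division distances through a lineage tree and
  module-averaged lineage-distance matrices.
- **Synthetic data.** A planted-partition connectome generator (directed
  links, geometric multiplicities, symmetric gap junctions, module-aligned
  positions, noisy ganglion labels, optional clade-aligned lineage trees)
  writing the same table dialect the readers consume, so the entire
  pipeline runs without any download.

## Worked example

Generate a 60-neuron, 3-module synthetic connectome and run the full
pipeline:

```sh
mesoconn synth --n 60 --modules 3 --seed 1 --out demo
mesoconn run-all --neurons demo/neurons.tsv --connections demo/connections.tsv \
    --tree demo/lineage.csv --replicates 5 --seed 1 --out demo_out
```

prints (abridged):

```
ingest:
  n: 60
  L: 599
  W: 1204.0
modules:
  Q_groups: 0.375298
  Q_spectral: 0.60496
  modules: 3
  NMI_groups_vs_modules: 0.6293
  Q_randomized_mean: 0.235242
  Q_randomized_sd: 0.016681
stats:
  SCC: 60
  IN: 0
  OUT: 0
  efficiency: 0.491375
cost:
  DW: 35.816666
  CW: 20.488954
```

Reading: the spectral optimizer finds the three planted modules with
Q = 0.605, far above both the modularity of the noisy "ganglion" labels
(0.375) and the degree-preserving null ensemble (0.235 ± 0.017) — the
network is strongly modular, and the ganglia only partially align with the
modules (NMI 0.63). The whole network is one strongly connected component,
and its dedicated-wire cost (35.8 body lengths) is far below the ~163 of a
typical degree-matched rewiring, at the price of lower efficiency: the
wiring-economy trade-off the cost stage quantifies.

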