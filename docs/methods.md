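# Methods

This note documents the models, conventions and numerical choices behind
`mesoconn`, and what the synthetic-data tests do and do not establish
about real connectomes.

## Network construction

The connection table lists each chemical synapse from both sides (send
codes `S`/`Sp` and receive codes `R`/`Rp`) and each gap junction (`EJ`),
with `NMJ` rows recording neuron-to-muscle junctions. Construction rules:

- A receive record `(a, b, R, n)` is the mirror of a send record
  `(b, a, S, n)`. Receive records whose mirror send exists are dropped to
  avoid double counting; an unmatched receive record is reversed into a
  send edge. (The dataset convention does not say how one-sided receive
  rows should be treated; reversal keeps the synapse rather than
  discarding it.)
- Gap junctions are symmetric. Tables conventionally list them from both
  sides with equal multiplicity; the two orientation sums are collapsed by
  taking their maximum (with a warning when they disagree), so one-sided
  and two-sided listings produce the same weight.
- Neuromuscular rows are parsed but excluded from every network mode:
  they are not neuron-neuron links.
- Self-loops are removed; the modularity null model and the degree
  definitions assume none.
- Three modes: `gap` (undirected, held mirrored in the directed view),
  `syn` (directed), `combined` (weights summed per ordered pair).
  `weighted=False` binarizes each channel before combining.
- Positions are one-dimensional (fraction of body length along the
  longitudinal axis); any transverse structure is deliberately ignored.

Under these rules the directed view satisfies Σ k_in = Σ k_out = L,
W(combined) = W(gap) + W(syn), and W = L after binarization; the test
suite asserts all three.

## Modularity and its optimization

Q is always *reported* through the directed weighted form
Q = (1/W) Σ_ij [w_ij − s_i^out s_j^in / W] δ(c_i, c_j); for a mirrored
undirected network this is algebraically the classical 2m-normalized
form, which the disjoint-triangles oracle (Q = 1/2) checks exactly.

The optimizer is recursive spectral bisection on the symmetrized
generalized modularity matrix:

1. Form B_ij = w_ij − s_i^out s_j^in / W; work with (B + Bᵀ)/2. For a
   subgroup g, subtract the diagonal correction diag(Σ_{k∈g} row sums) so
   the split objective is exact (ΔQ = sᵀ B^(g) s / 2W for s ∈ {±1}).
2. Split by the sign of the leading eigenvector when its eigenvalue is
   positive. The eigenvector orientation is canonicalized (largest-|entry|
   component positive, first index on ties) and exact zeros join the
   positive side, making output deterministic. Dense symmetric solvers
   are used below 500 nodes, Lanczos above, tolerance 1e-10.
3. Refine each split by greedy single-node exchanges between the two
   sides: first-improvement sweeps in ascending node-name order, repeated
   until no move helps; a side is never emptied. (Whether moves should be
   first- or best-improvement is not determined by the published
   procedure; first-improvement with a fixed order is deterministic and
   cheap.)
4. Reject a split whose refined ΔQ ≤ 1e-12; recurse on accepted halves.
5. After recursion, run the same node moves *globally*: each node may
   relocate to any existing module while total Q increases. Recursive
   bisection alone cannot revise an early cut that slices through a true
   module; on planted-partition benchmarks this final pass is what closes
   the gap between the found and planted optima (observed on one of ten
   benchmark seeds at n = 120, M = 4).

Sanity bounds: on graphs of ≤ 8 nodes the optimizer never exceeds the
exhaustively enumerated best Q over labelings into ≤ max(3, M̂) modules,
and the reported Q always equals the score recomputed from the returned
partition.

## Partition and group comparison

NMI uses the overlap-matrix form with natural logarithms (the base
cancels). Degenerate inputs follow the formula's limit: a single-block
partition yields 0 against anything non-trivial and 1 against another
single block. The implementation is cross-checked against an independent
arithmetic-mean NMI implementation in the tests.

Modular spectra are fraction vectors over modules; group distances are
Euclidean in that space. Physical distance between groups is the mean
|x_i − x_j| over cross-group pairs. Dendrograms use average-linkage
(UPGMA) agglomeration — no linkage is canonical for this application, and
UPGMA is the least structured default. Tree similarity is the Pearson
correlation of leaf-pair path-length matrices, where path length counts
edges in the binary merge tree. Module density matrices count realized
directed links over possible ordered pairs (n_a(n_a−1) on the diagonal).

## Global statistics

Shortest paths are topological everywhere — every link counts 1 even on
weighted networks — because path length here models the number of
synaptic hops a signal traverses, not a traffic-weighted distance.
Betweenness is the unnormalized pair-fraction sum (Brandes-style
counting, verified exactly against a brute-force path-enumeration oracle
on 100 random digraphs of ≤ 10 nodes). Efficiency averages 1/d over
ordered pairs, with disconnected pairs contributing 0. The bow-tie uses
the largest strongly connected component; tendrils are lumped with the
disconnected remainder. Assortativity is the Pearson correlation of total
degrees (k_in + k_out) across the ends of every directed edge — the
undirected convention applied to the directed edge list, since no directed
variant is canonical here. knn(k) averages total degree over each node's
unique in- ∪ out-neighbors.

## Wiring cost and the trade-off frontier

Dedicated-wire cost sums |x_i − x_j| over distinct connected unordered
pairs — multiplicity does not multiply cost, because the model prices
wire, not traffic. Common-wire cost sums each neuron's distance to its
farthest connected partner, the cheapest single-process layout.
Both are translation invariant and non-negative. The frontier is traced
by degree-preserving rewiring with positions fixed; each replicate gives
one (cost, efficiency) point per model, binned (20 equal-width bins) only
for plotting.

## Randomization

Directed edges are rewired by the pair-swap move (a→b, c→d) ⇒ (a→d, c→b),
aborting any swap that would create a self-loop or duplicate edge; gap
junctions are swapped as undirected pairs to preserve their symmetry, and
the combined network is randomized channel by channel. Edges whose node
pair carries both a synapse and a gap junction are frozen and swaps may
not create new cross-channel overlaps; this keeps the combined directed
view's in/out degree sequence exactly invariant (not only per channel) at
the price of slightly reduced mixing. Weights travel with their out-stub,
conserving W. The default is 10×L attempted swaps per replicate, a
standard mixing heuristic. The modularity-constrained variant draws both
edges of a swap from the same ordered module-pair class, which preserves
every node's module-resolved degree — the property the role-to-role null
requires.

`ensemble_stat` derives replicate seeds as seed + i, reports mean, sample
sd and z = (empirical − mean)/sd, flagging sd = 0 ensembles instead of
dividing by zero.

## Cartography

Degrees in z and P are unweighted in+out link counts. κ is the node's
link count into its own module; z standardizes κ within each module with
the population sd, and modules with zero κ-variance assign z = 0 to all
members. P = 1 − Σ_m (κ_m/k)², 0 for isolated nodes (flagged). Role
cutoffs follow the standard cartographic scheme — hub threshold z* = 2.5,
non-hub P cuts 0.05/0.62/0.80, hub P cuts 0.30/0.75 — and are all
configurable. Role-to-role z-scores fix roles at their empirical
assignment and recount links per constrained replicate; recomputing roles
per replicate would conflate role drift with link abundance. The paper
trail for this statistic uses 10³ replicates; that is the library default,
while tests and the demo pipeline use tens of replicates to keep runtimes
in seconds (the statistic's seed and n are always recorded in outputs).

## Lineage

Distance counts cell divisions via the last common progenitor, with the
first division out of that progenitor counted once: sisters are at
distance 1, first cousins at 3. For ancestor-descendant pairs the
distance is the number of divisions between them, with no discount; this
convention (not forced by the published definition) keeps parent-child
distance 1 and is stated rather than inferred. A precomputed pairwise
distance matrix may replace the tree. Module matrices average pairwise
distances within (diagonal) and across (off-diagonal) modules; singleton
modules get a flagged NaN diagonal.

## Synthetic generator

The generator emulates the statistical structure the analyses assume:
modules denser inside than out (directed planted partition, defaults
n = 120, M = 4, p_in = 0.5, p_out = 0.02 — a clear but not trivial
contrast), geometric edge multiplicities with mean 2 (mimicking the
exponentially decaying, non-heavy-tailed strength distributions of real
somatic connectomes, and making weighted and unweighted analyses diverge
measurably), a 0.25 fraction of links realized as symmetric gap junctions
(roughly the proportion of electrical contacts in such data), per-module
Gaussian position clusters (sd 0.06 on the unit body axis), ganglion
labels equal to the planted module with 15% noise, and optional
clade-aligned binary lineage trees. Channel type is decided per unordered
pair, and gap pairs use a single Bernoulli draw mirrored to both
directions, so every ordered pair's link probability is exactly
p_in/p_out and generator parameters remain the density oracle for tests.

What passing synthetic tests show: the pipeline's operations are correct
on networks with planted, known structure, at effect sizes typical of the
real system. What they do not show: correct recovery under the real
connectome's degree heterogeneity, reciprocity and spatial layout, which
no planted-partition model reproduces; the real-data reference tests
(which require the non-redistributable wiring tables on disk) cover that
ground when the data are present.

## Problem sizes in tests and the demo

Test and demo ensembles use 5–50 replicates and networks of 40–120 nodes;
the acceptance script uses a 60-node network. These sizes were chosen so
the full suite runs in well under a minute while every statistical
assertion retains a ≥ 3-sigma margin; library defaults (100 replicates for
scalar ensembles, 1000 for role-to-role) are what an analysis of a real
connectome would use.
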