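# Methods

## Model

A connected undirected network of *n* genes is modelled as a Gaussian
network: nodes are beads, edges are identical springs of constant γ, and the
connectivity is the Kirchhoff/Laplacian matrix Γ (degree on the diagonal,
−1 for edges). Γ is singular with nullity equal to the number of connected
components, which is why the pipeline requires the giant component before
building the model. The covariance of the equilibrium fluctuations is
C = (1/γ) Γ⁺, computed by dense symmetric eigendecomposition and inversion
of the nonzero modes. Numerical choices:

- **Zero-mode tolerance.** An eigenvalue counts as zero when it is below
  `1e-8 × λ_max` (relative, so robust to network size). Exactly one
  near-zero eigenvalue is required; more indicates a disconnected input and
  is an error rather than a silent repair.
- **Size contract.** Dense eigendecomposition is the contract up to 10,000
  nodes (the published genome-scale networks are ~5,000 nodes, minutes on
  one core). Larger inputs are rejected explicitly; no sparse or iterative
  approximation is attempted.
- **γ.** Defaults to 1 and is exposed only for completeness: it rescales C
  uniformly and cancels in the PRS normalization, so all reported quantities
  are in arbitrary units.

## Perturbation-response scanning

Perturbing node *i* with a unit force gives responses proportional to row
*i* of C. Normalizing by the perturbed node's own variance σᵢ = Cᵢᵢ removes
the topology-defined adaptability bias and breaks the symmetry of C. Two
conventions are implemented:

- `squared` (default): P_ij = C_ij² / C_ii². Responses are squared
  magnitudes, nonnegative, with P_ii ≡ 1. This is the convention under
  which "magnitude of response" is well defined, and it matches the
  established PRS implementations for elastic network models.
- `linear`: P_ij = C_ij / C_ii, the literal linear-response form, kept for
  comparison; rows contain negative entries.

Effectiveness is the row mean of P, sensitivity the column mean. The
diagonal (constant 1) is included by default; excluding it shifts every
profile by the same constant and cannot change any ranking, and a toggle is
provided. The grand mean of effectiveness equals the grand mean of
sensitivity exactly (both are the grand mean of P) — this identity is
asserted in the tests to machine precision.

### Clustering the PRS matrix

The "distinct" perturbed/responding gene clusters come from hierarchical
clustering of the rows (perturbed axis) or columns (responding axis):
entries above the 95th percentile of the whole matrix are winsorized to that
percentile (the winsorization quantile is computed over all n² entries, not
per row), pairwise distances are standardized Euclidean (per-coordinate
variance across observations; zero-variance coordinates dropped with a
logged notice), linkage is Ward, and the tree is cut at the top-level merge
into two clusters, of which the smaller is reported. A singleton split is
reported but flagged degenerate.

## Node classes

- **Selection.** k = round(fraction × n), rounding half away from zero —
  the only rule consistent with the three published selection sizes
  (5,183 → 52 and 3,238 → 32 at 1%; 1,145 → 57 at 5%). Ties at the k-th
  value break by descending value then ascending node label.
- **Clusters.** Connected components of the member-induced subgraph with at
  least 3 members (configurable); smaller components are kept as
  "unclustered" members.
- **Antenna motifs.** A cluster is an antenna iff exactly one non-member
  node is adjacent to any member. A cluster spanning the whole network has
  no exterior and the check is an error.
- **Neighbor-degree comparison.** Average neighbor degree of class members
  vs all other nodes, compared by the unpaired Mann–Whitney rank-sum test.
  No natural pairing exists between a class of k nodes and the n−k others,
  so the unpaired form is the defensible choice.
- **Edge enrichment.** The observed statistic is the percentage of the
  class's edge endpoints that land inside the class. Null samples draw, per
  member, a distinct uniformly random node of identical degree (class
  members remain eligible — excluding them would bias the null); when an
  exact degree class is exhausted within a sample the nearest available
  degree is used, logged. Fold is observed over null mean; the p-value is
  the empirical (r+1)/(n+1) with ties counted as exceedances.

## Null models and tests

Degree-preserving nulls are produced by connected double-edge swaps: a swap
of two random edges is accepted only if it creates no duplicate or self
edge and leaves the network connected, and at least 10 × |E| accepted swaps
are performed per replicate (the multiplier is configurable). Networks too
small to admit any swap are returned unchanged with a warning. A master
seed spawns per-replicate seeds, so ensembles are bit-reproducible.

All empirical p-values use p = (r+1)/(n+1), counting ties as exceedances
(conservative), with an explicit one-sided direction; p is therefore never
0 and never exceeds 1. The label-shuffling permutation test on
mean(group) − mean(rest) defaults to 10,000 shuffles.

## PRS paths

Node weights for a path starting at gene *i* are row *i* of P. Among all
unweighted shortest paths to the target, the one maximizing the summed node
weight (endpoints included) is selected by exact dynamic programming on the
BFS shortest-path DAG — correct even when the number of distinct shortest
paths is exponential, and validated against exhaustive enumeration on small
graphs. The source's self-response (always 1) is a constant across
candidates and never changes the argmax. Ties break to the
lexicographically smallest node sequence. Between two clusters, the
highest-total-weight path over all member pairs is selected (raw total, not
length-normalized, matching "highest total perturbation effect"; a per-node
mean option exists), with ties broken by shorter path then lexicographic
order.

## GO enrichment

OBO ontologies are parsed with `obonet`; GAF 2.x annotation files with a
small built-in reader (NOT-qualified rows dropped). Evidence codes ND, IGI
and HGI are excluded by default so that annotations derived from genetic
interactions cannot circularly validate a genetic-interaction network.
Annotations are restricted to the background population (the network's
nodes). Per term, over-representation is the one-sided Fisher exact test
(hypergeometric upper tail). The resampling FDR re-runs the whole battery
on 500 random study sets of identical size (the same sets reused across
terms) and reports per term (r+1)/(n+1) with r the number of random sets
achieving a p-value at most the observed one; FDR < 0.1 is the default
significance call. Annotations are not propagated to ancestor terms by
default; a `propagate` option climbs is_a/part_of edges.

## Synthetic fixtures

The planted generator emulates the topology in which sensors arise in real
profile-similarity networks: a dense Erdős–Rényi core (default 30 nodes,
edge probability 0.4 — dense enough that the core is reliably connected and
contains clear hubs) plus clique antennas (default 3 antennas of 4 nodes;
cliques of size 3–6 are the motif shape of interest) each joined to a core
node of median degree by a single edge. Median-degree connectors make the
antenna members' sensitivity attributable to the motif topology rather than
to connector degree. The annotation fixture gives each antenna one fully
penetrant signal term plus background terms annotating 10% of genes
uniformly at random.

What the fixtures do *not* emulate: the heavy-tailed degree distribution,
the size (thousands of nodes), and the correlated edge structure of real
similarity networks. Passing the planted-recovery tests therefore shows the
pipeline detects the antenna mechanism when present, not that real networks
contain it.

## Problem sizes in the test and acceptance runs

Oracle comparisons use 100 random connected graphs of up to 50 nodes
(covariance) and 30 nodes (paths); calibration suites use 200 label
shuffles at 199 permutations each; the planted-recovery sweep uses 20
generator seeds with 5 rewired replicates each; enrichment calibration uses
10 random study sets at 100–500 resamples. These sizes give stable pass/fail
behavior at sub-minute runtimes; all of them are parameters, not limits.

## Known limitations

- Dense linear algebra only; no support beyond ~10,000 nodes.
- Unweighted, undirected networks; similarity weights are used solely for
  thresholding.
- The rewiring stub for degenerate graphs (no valid swap) returns the input
  unchanged, so ensembles on tiny graphs under-disperse.
- GAF parsing keeps one gene identifier column (symbol or DB id); alleles
  or synonyms are not merged.
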