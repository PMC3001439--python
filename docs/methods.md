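# Methods

## Network construction

Input is a table of *directional* template-match records
`(query_id, target_id, rmsd, et_score)`. Both quantities are oriented so
that smaller means a better match: RMSD is the superposition error of the
matched residue template in Å, and the ETScore summarizes how much the
evolutionary importance of the matched residues differs. Self matches are
invalid input and rejected at parse time.

Match statistics (mean and population SD of RMSD and ETScore) are computed
over the raw directional records, before reciprocal collapsing — they
characterize the matcher's output distribution, of which each direction is
an independent draw. Duplicate records for one direction are averaged with
a warning.

An undirected edge {A, B} is created only when both A→B and B→A records
exist (reciprocal filtering); its RMSD and ETScore are the means over the
two directions. The weight standardizes each averaged quantity as
(µ − x)/σ — positive when better than average — takes the mean of the two
standardized terms, and maps through the logistic. This form was chosen for
three properties the adjacency definition requires: weights are strictly
positive, strictly decreasing in both RMSD and ETScore, and invariant to
affine rescaling of either input (so the units of ETScore are irrelevant).
A σ of exactly 0 means the quantity carries no discriminating information;
its term is defined as 0. The weight function is a pluggable strategy
(`build_network(weight_fn=...)`) so alternative forms can be substituted
without touching graph assembly.

The sequence-identity filter removes edges whose pairwise identity exceeds
a cutoff, emulating homology-ablation experiments; pairs with no identity
entry keep their edge (absence of homology evidence is not evidence against
structural similarity) with a logged warning. The filter is monotone: lower
cutoffs remove supersets of edges.

## Label diffusion

For a candidate function g at EC level k (3 or 4), the initial label of
node i is +1 if one of its ECs truncates to g, −1 if it carries at least
one complete-at-level EC and none equals g (only when negative labels are
enabled), else 0. Partial codes such as `3.1.-.-` at level 3 are never
negative evidence — they cannot establish that the protein lacks a
function. A multifunctional protein is +1 for each of its own functions
and never simultaneously +1 and −1 for one function.

The diffused labels solve `(I + αL) f = y` with the combinatorial Laplacian
`L = D − W`. This matrix is symmetric positive definite for α ≥ 0, and we
solve it by a sparse direct factorization computed once per network and
reused across all candidate functions; the relative residual is verified
against a 1e-8 contract on every solve. Key consequences used as test
oracles: `(I + αL)⁻¹` is nonnegative with unit row sums, so f is a convex
combination of the y entries and stays in [−1, 1]; α = 0 returns y; on a
connected graph α → ∞ drives every f_i to the mean of y; a connected
component with no labels has f ≡ 0 exactly.

A symmetric-normalized Laplacian (`I − D^{−1/2} W D^{−1/2}`, zero rows for
isolated nodes) is available behind the `laplacian="normalized"` switch but
is not the default: the combinatorial form keeps the α-limits above exact,
which anchors the closed-form tests.

α is a dimensionless coupling with no principled external value; the
default is 1.0, and `sweep-alpha` exposes a cheap sweep. On the planted
benchmarks accuracy is insensitive to α over at least an order of
magnitude.

## Confidence z-scores and competitive annotation

Raw f values are biased by label prevalence (a function with many +1 seeds
floods the network). Per function, f is therefore reduced over the
*unlabeled* nodes to z_i = (f_i − µ_f)/σ_f with population (divide-by-n)
mean and SD: this is a normalization over a fixed finite node set, not an
inferential estimate, so no Bessel correction is applied. If σ_f < 1e-12
all z are 0 (no signal). The winning function at a query is the argmax of
z; ties break toward the numerically smallest EC code so output is
deterministic.

Queries are withheld (their labels forced to 0) either all at once
(`holdout="batch"`, matching a test-set protocol) or one at a time
(`holdout="loo"`, leave-one-out). Queries whose connected component
contains no labeled node still receive the argmax-z function but are
flagged `isolated=true` rather than silently dropped.

The nearest-neighbor baseline sums edge weights from a query to its
directly adjacent labeled nodes per function, predicts the largest sum, and
reports the mean weight of the winning edges as confidence. Its coverage
gap — silence whenever no direct neighbor is labeled — is exactly the gap
diffusion closes, which the bridge-cluster fixture demonstrates.

## Evaluation

Predictions are sorted by descending confidence and one cumulative point is
emitted per distinct confidence value (equal-confidence predictions enter
together, so the curve is order-independent): accuracy = tp/(tp+fp),
coverage = (tp+fp)/test_size, sensitivity = tp/(tp+fn) where correct
predictions below the threshold count as false negatives, precision =
tp/(tp+fp). A prediction is correct if it matches *any* of the node's truth
ECs at the evaluation level — exact-set matching would penalize promiscuous
enzymes. "Accuracy at coverage c" means the deepest curve point with
coverage ≤ c.

The negative-label ablation runs the competitive annotator twice (with and
without −1 labels) and reports both curves plus their accuracy difference
on a coverage grid. The shortest-path diagnostic bins unweighted hop
distances from correctly predicted nodes to every labeled node, split by
same vs different function and by confidence bin (default z edges 0, 1, 2,
3; unreachable pairs are dropped).

## Synthetic benchmarks

Real match networks require the full evolutionary-trace and geometric
matching pipeline, which is out of scope; benchmarks are planted-partition
graphs instead. Each function is a block of nodes; node pairs are joined
with probability p_in within a block and p_out across blocks, and every
realized edge is emitted as two directional records (so reciprocal
filtering keeps it) with RMSD/ETScore drawn from zero-truncated normals —
within-block edges from a better distribution (defaults 1.0 ± 0.3) than
between-block ones (2.5 ± 0.5). The default conditions are 5 functions ×
30 nodes, p_in = 0.3, p_out = 0.01, half of each block labeled, chosen as a
clearly clustered but not block-diagonal regime: expected within-degree
≈ 8.7 against ≈ 1.2 background edges per node. Synthetic ECs are valid
four-component codes ("1.1.1.1", "2.1.1.1", …) so level-truncation logic is
exercised end to end.

These generators reproduce the one property the method exploits — functions
cluster in the similarity network — and none of the confounders of real
data: no correlated match errors, no heavy-tailed degree distributions, no
annotation noise or database bias, and a single function per protein.
Passing the planted benchmarks therefore validates the machinery
(construction, diffusion, calibration, ranking), not performance on real
proteome-scale networks. At the default settings the planted problem is
cleanly separable, so both annotators can reach perfect accuracy and the
ablation difference is zero; the fixtures that probe the regimes where the
methods differ (bridge topology, two-cluster negative-label flip) are
hand-built instead.

The bridge-cluster fixture is a fixed 12-node graph: a query whose direct
neighbors are all unlabeled, a labeled 4-clique two hops away, and a
detached unlabeled ring that supplies background variance for the z-score.
The nearest-neighbor baseline makes no prediction for the query; diffusion
assigns the clique's function with z ≈ 0.32.

## Numerical and design notes

- Solver: `scipy.sparse.linalg.factorized` (sparse LU) on the CSC matrix;
  for the SPD systems at desk scale this is exact to machine precision and
  one factorization serves all functions and both ablation arms.
- Population SD throughout (match statistics and z-scores).
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeds; identical inputs and configuration give byte-identical output
  files, and prediction TSVs are sorted by (confidence desc, node id).
- Degenerate inputs: empty record sets give empty networks; a single match
  record gives σ = 0 statistics and weight 0.5; blocks of size 1 with
  p_in > 0 warn; zero unlabeled nodes is an error ("nothing to predict").
- Known limitations: EC hierarchy only (no GO DAG labels), one winning
  function per query, α is not learned from data, and the match records
  and sequence identities themselves are inputs — the package neither runs
  template matching nor computes alignments.
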