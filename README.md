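# etadiffuse

Enzyme-function annotation by **competitive diffusion of Enzyme Commission
(EC) labels** over a network of local structural/evolutionary protein
similarities.

Structural genomics solves many protein structures whose molecular function
is unknown. Evolutionary-trace template matching (ETA) detects pairs of
proteins that share a small set of evolutionarily important surface residues
in the same 3D arrangement — a strong hint of shared biochemistry. This
package takes such directional match records (query chain, matched chain,
superposition RMSD in Å, and an evolutionary-similarity ETScore), turns the
*reciprocal* matches into a weighted similarity network, and lets every
known enzymatic function diffuse over that network to annotate the
unannotated nodes. It is aimed at computational biologists who have a table
of pairwise match records and reference EC annotations and want calibrated,
confidence-ranked function predictions.

## Model

Nodes are protein chains; a reciprocal match (A matched B *and* B matched A)
becomes an undirected edge. The per-pair RMSD and ETScore are averaged over
the two directions, standardized against the full record set, and mapped
through a logistic, so every edge weight satisfies 0 < w_ij < 1 with
better-than-average matches above 0.5:

    w_ij = σ( ½ [ (µ_rmsd − rmsd_ij)/σ_rmsd + (µ_ET − ET_ij)/σ_ET ] ),
    σ(s) = 1 / (1 + e^(−s))

For each candidate function, every node gets an initial label y_i ∈
{+1, −1, 0}: +1 if it is known to have the function, −1 if it is known to
have a *different* function, 0 if there is no evidence either way. The
diffused labels f minimize the quadratic cost

    Σ_i (f_i − y_i)² + α Σ_{i<j} w_ij (f_i − f_j)²

whose unique minimizer solves the sparse symmetric-positive-definite system

    (I + αL) f = y,   L = D − W,   D = diag(Σ_j w_ij)

The coupling α balances smoothness along edges against fidelity to known
labels (α = 0 returns the inputs; α → ∞ flattens f to the component mean).
Because functions differ wildly in prevalence, f is normalized per function
into a z-score over all unlabeled nodes, z_i = (f_i − µ_f)/σ_f, and each
query is annotated with its highest-z function; the z value is the
confidence. A nearest-neighbor baseline (cumulative edge weight to directly
adjacent labeled nodes) is included for comparison — unlike diffusion, it is
silent whenever a query has no labeled neighbor.

## Worked example

Simulate a planted benchmark (3 functions × 12 chains, within-function edge
probability 0.5 vs 0.02 background, half the chains labeled), build the
network, and annotate the withheld half:

```bash
cat > sim.yaml <<EOF
n_functions: 3
nodes_per_function: 12
p_in: 0.5
p_out: 0.02
EOF
etadiffuse simulate --config sim.yaml --seed 11 -o sim
etadiffuse build-graph --matches sim.matches.tsv -o graph
etadiffuse predict --graph graph --labels sim.labels.tsv \
    --queries sim.queries.txt --level 4 --alpha 1.0 -o preds.tsv
head -4 preds.tsv
```

```
node    function    confidence          method     isolated
p01006  2.1.1.1     1.5934783965937414  diffusion  false
p00007  1.1.1.1     1.5929150747317238  diffusion  false
p00011  1.1.1.1     1.5461255212901701  diffusion  false
```

Each withheld chain receives the EC code whose diffusion z-score is highest
at that node; `p01006` is assigned the function planted in its block with a
confidence 1.59 standard deviations above the unlabeled-node mean. Scoring
the predictions against the withheld truth:

```bash
etadiffuse evaluate --predictions preds.tsv --truth sim.truth.tsv \
    --level 4 --test-size 18 -o eval
# INFO etadiffuse: full-coverage point: accuracy 1.000 at coverage 1.000
```

All 18 withheld chains are recovered correctly (accuracy 1.0 at coverage
1.0); `eval.curve.csv` holds the full confidence-stratified curve. The same
surface is available as a library of sklearn-style estimators:

```python
from etadiffuse import DiffusionAnnotator, build_network, io
net = io.read_network("graph")
ann = DiffusionAnnotator(alpha=1.0, level=4).fit(net, io.read_label_table("sim.labels.tsv"))
ann.predict(io.read_query_list("sim.queries.txt"))
```

Other subcommands: `nn-predict` (baseline), `ablate` (negative-label
ablation), `path-hist` (shortest-path diagnostics), `sweep-alpha`, and the
`--identities/--max-identity` options of `build-graph` for the
sequence-identity edge filter.

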