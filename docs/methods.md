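# Methods

## Model and pipeline

`coevnet` treats a query-anchored MSA as a sample of realizations of each
alignment column and asks, for every column pair, how far their joint
residue distribution departs from independence. The pipeline is: trim the
alignment to the query's ungapped columns → compute per-sequence phylogeny
weights → compute a coupling matrix with one of three metrics → optional
post-processing and graphical-LASSO regularization → residue graph,
maximal cliques and functional-site enrichment.

### Phylogenetic weighting

Each sequence is weighted by the inverse size of its identity neighborhood:
w_a = 1 / #{b : seqid(a, b) > t}, t = 0.80 by default, with the sequence
itself in the neighborhood so that every weight lies in (0, 1] and isolated
sequences keep weight 1. Identity is defined as identical residue pairs over
mutually non-gap columns; a sequence pair sharing no non-gap column has
identity 0, and the unknown residue `X` never matches anything (itself
included). These two conventions are the package's own choices, made for
robustness on gappy homologs; the threshold comparison is strictly `>`.
A group of k exact duplicates therefore carries total weight 1, and every
pairwise statistic is invariant (to floating-point precision) under
replicating the entire alignment — a property the test suite asserts.

### Pair probabilities

For columns (i, j), sequences with a gap or `X` at either column are
excluded; N_eff is the weight sum of the rest. Every state probability is a
weighted count divided by N_eff + 1. These probabilities are deliberately
sub-normalized — they sum to N_eff/(N_eff + 1) — and are consumed by the
metrics exactly as defined, with no renormalization: renormalizing would
silently rescale every score and shift every downstream cutoff. The single
pseudo-count lives in the denominator only. Marginals are row/column sums
of the joint table, so they are consistent with the same included-sequence
set. A pair with N_eff = 0 is degenerate: its score is undefined, masked,
exported as `NA`, and treated as below any cutoff.

One consequence worth knowing: because probabilities never reach 1, a pair
of perfectly coupled balanced binary columns has chi2 ≈ [(2 − t)² + t²]/2
with t = N_eff/(N_eff + 1), i.e. ≈ 1.0 for deep alignments — so
CDF-transformed chi2 scores saturate near chi2-CDF(1) ≈ 0.68 on the
2-letter alphabet. "High" cutoffs for this metric are therefore ≈ 0.5–0.65,
not 0.9. Similarly, a single sequence yields MI = ½ ln 2 and chi2 = ¼ for
every pair: no pair is distinguished (the scores carry no discriminating
information), but the values are not literally zero.

### Metrics

* **MI** uses the natural logarithm (nats). The base is a pure rescaling;
  nats are the convention in the coupling-analysis literature, and all
  cutoffs in this package are on the same scale.
* **chi2** sums over states with nonzero expected probability; it is
  post-processed through the chi-squared(df = 1) lower-tail CDF into [0, 1]
  (`scipy.stats.chi2`). Raw scores are available via `post_process=False`.
* **pearson** correlates the PSSM substitution scores realized by the two
  columns. Means and standard deviations are weighted *population*
  statistics (divide by N_eff, matching the 1/N_eff prefactor of the
  correlation itself) computed over the pairwise non-gap subset — the same
  sequences that enter the cross term — rather than over all sequences of
  each column separately; this keeps the estimate internally consistent and
  |r| ≤ 1 up to rounding. r is clipped into [−1, 1] before taking the
  absolute value. Columns whose realized scores are constant (σ = 0) give
  an undefined correlation and are masked.

Diagonal entries are computed and exported in matrix files but excluded
from graphs, cliques and enrichment counting (couplings are between
*different* positions). The 2-letter alphabet encodes each residue as
match/mismatch to the query's residue at that column; the 20-letter
alphabet uses the amino acids themselves. Gap-as-21st-state alphabets and
average-product correction are out of scope.

### Graphical LASSO

`glasso_estimate` wraps scikit-learn's coordinate-descent graphical lasso,
which, like PSICOV's usage, leaves the diagonal of the precision matrix
unpenalized. An independent block-coordinate-descent implementation in the
test suite confirms the solution to 1e−6. "Feasible" at a given ρ means the
outer loop converged within the iteration cap (default 100) with no NaN/Inf
in either the estimated covariance or its inverse; inner-lasso convergence
warnings are advisory and ignored. `auto_rho` performs bisection over the
0.01-spaced grid in (0.01, 0.99) for the smallest feasible ρ, assuming
feasibility is monotone in ρ (stronger regularization only improves
conditioning); under that assumption it returns exactly what a linear grid
scan would. Post-processed matrices (CDF-transformed chi2, |r|) are fed to
the estimator as-is — they are couplings, not classical covariances, and
regularizing the same matrices the rest of the pipeline consumes keeps the
two views consistent; raw-chi2 input is available by computing the matrix
with `post_process=False`. Masked entries are imputed before estimation: 0
off-diagonal (independence) and 1 on the diagonal — a zero diagonal would
make the log-det objective undefined at every ρ, so the metric's natural
self-coupling scale is used and the imputation count reported.

### Graphs, cliques, conservation

A residue graph at cutoff c keeps all L positions as nodes and connects
unmasked pairs with score ≥ c and |i − j| ≥ `min_separation` (default 1:
only self-pairs are excluded, since functionally coupled residues are often
sequence-adjacent). Maximal cliques come from networkx (Bron–Kerbosch with
pivoting) and are canonicalized — members sorted, cliques ordered by size
descending then lexicographically — so outputs are reproducible regardless
of enumeration order. Cliques of size ≥ 2 are reported; singletons remain
visible as isolated nodes. Node conservation is the Shannon entropy of the
weighted residue frequencies of the column, excluding gaps and `X` and
renormalizing over the remaining weight (conservation of residues, not
occupancy; a flag includes the gap as a 21st symbol), normalized by ln 20
into [0, 1]. The cutoff sweep reports non-isolated node, edge and clique
counts plus clique-size statistics over an ascending grid (default
0.1–0.9 step 0.1); edge sets are nested across the grid by construction.

### Enrichment statistics

LO uses the natural log. Its NA rule is exactly "zero or undefined argument
to the logarithm": r = 0, n = 0, or R_f ≤ 1. NA values never enter pooled
densities or P(LO); their count is carried alongside. P(LO) is the
empirical survival fraction (≥ cutoff) of the finite LO values. In the
clique variant, a member of the clique counts toward n even when its direct
coupling with the residue of interest is below the cutoff — clique
membership, not direct coupling, defines the group. Because a residue can
sit in several maximal cliques, Table-style per-residue clique reports show
the *maximum* LO over the cliques containing the residue (the residue's
best coevolving group); this is a reporting choice, the per-clique API is
exposed. Site-separation distributions use differences between
*consecutive* sorted same-category positions within a protein (the three
default bins 1–4, 5–29, 30–1000 then partition 100%); an all-pairs variant
sits behind a flag. Propensities pool annotated residues across proteins;
the background frequency is computed over all residues of the supplied
sequence set, and zero-observation cells are NA rather than −∞. Residues
annotated with several ligand categories count once per category —
categories are analyzed independently.

### Synthetic data

The generator plants couplings via a latent binary state per sequence: with
probability `strength` both columns of a pair jointly show either the query
residue or a fixed per-column alternative; otherwise both columns are
independent background draws. This makes `strength` directly the fraction
of sequences carrying the coupled signal, and strength 1.0 a perfectly
correlated pair under the 2-letter encoding. Redundancy groups mutate a
base homolog at < `mutation_rate`/2 of the non-planted positions per
member, so any two members differ at < `mutation_rate` (default 0.1,
bounded below 0.2) of positions and the whole group stays above the 80%
identity threshold. Defaults: uniform residue background (a skewed
natural-composition preset is provided for propensity tests), gap
probability 0 per position (settable), first sequence the gap-free query.
The test conditions used throughout — 50 columns, 200 sequences, coupling
0.9, 20 seeds — are the package's standard desk-scale configuration and are
also what `scripts/acceptance.py` reruns. What the generator does *not*
emulate: tree-structured phylogenies, correlated gap patterns, alignment
errors, or contact-driven (structural) couplings. Passing tests demonstrate
the statistics behave as specified on controlled signals, not that any
particular biological alignment will show the same contrast.

### Degenerate inputs and numerical conventions

* Non-standard residue letters (B, Z, J, U, O, and anything unrecognized)
  are read as `X`; `X` is excluded from pair counting, identity matching and
  entropy alike.
* All-gap columns, single-sequence alignments and empty annotation sets are
  processed, yielding masked scores, undistinguished pairs and empty tables
  respectively rather than errors.
* Matrix symmetry is enforced to 1e−12 on construction; MI ≥ 0 is asserted
  to 1e−12 tolerance in tests.
* The benchmark redundancy filter (< 25% pairwise identity, ≥ 30 aa, ≥ 100
  homologs) is greedy in input order with a pluggable identity function
  (default: global pairwise alignment matches over the longer length); it
  is a utility, not a reconstruction of any particular clustering.

## Known limitations

* The 2-letter chi2 statistic is sensitive to rare-match coincidences in
  shallow alignments (a single co-occurring query match can score like a
  perfect coupling); deeper alignments and the CDF's bounded range temper
  but do not remove this.
* `auto_rho`'s monotone-feasibility assumption can be violated by borderline
  convergence at isolated grid points; in that event bisection may return a
  feasible ρ that is not the global grid minimum.
* Propensity and distance summaries are only as good as the annotation
  coverage; unannotated true sites deflate LO and propensity alike.
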