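# Methods

This note records the model, the numerical choices, and the design
decisions behind the package, together with what the synthetic benchmark
does and does not establish.

## Fuzzy coding and the correspondence model

Raw counts are used directly.  Each gene `j` is doubled into a fuzzy
presence/absence pair using its per-gene minimum `m1ⱼ` and maximum `m2ⱼ`
as hinge points of a piecewise-linear membership function:
`Z⁺ = (Y − m1)/(m2 − m1)`, `Z⁻ = 1 − Z⁺`.  Because `Z⁺ + Z⁻ = 1`
row-wise, the correspondence matrix `P = Z/(np)` has exactly uniform row
masses `rᵢ = 1/n`; column masses `c` are the column sums of `P`.  Genes
constant across all cells (including genes detected in no cell) make the
coding undefined and carry no information; they are **dropped with a
warning** rather than imputed, and the dropped ids are reported by the
pipeline.  Columns are stored interleaved as (j⁺, j⁻) pairs so the later
"keep only the + categories" step is an even-index slice.  `Z` is dense by
construction (fuzzy coding destroys sparsity), so sparse inputs are
densified during coding.

## MCA decomposition

The standardized Pearson residuals
`R = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}` are decomposed by SVD.  Exact LAPACK
SVD is used when `min(n, 2p) ≤ 400`; above that, an iterative truncated
solver with a seeded starting vector (identical results across runs).  The
sign of each component is fixed by requiring the largest-magnitude entry
of each right singular vector to be positive — every downstream quantity
is provably invariant to component signs, so this is cosmetic
reproducibility only.

Cells get standard coordinates `Φ = D_r^{-1/2}U`; gene categories get
principal coordinates `G = D_c^{-1/2}VΛ` (the column-principal asymmetric
biplot, which supports the distance interpretation used downstream).  Only
the `+`-category rows of `G` are retained.

A geometric consequence of the doubling worth stating precisely: for every
gene, `c⁺g⁺ + c⁻g⁻ = 0` holds exactly — the *mass-weighted* average of the
two category points is the origin, and the two points are anti-collinear
through it (componentwise opposite signs).  The unweighted sum `g⁺ + g⁻`
is zero only when the two categories happen to carry equal mass; the
package's tests assert the mass-weighted identity, which follows directly
from `Z⁺ + Z⁻ = 1`.

The number of components `K` defaults to 60 (clamped to
`min(n, 2p) − 1`), appropriate for full-size data with on the order of
10⁴ genes.  Because cells are clustered in *standard* coordinates — all
retained dimensions enter distances with equal weight — `K` should track
the number of meaningful components.  On the scaled 2,000-gene benchmark
(five populations; singular-value spectrum flat beyond the first ~10
components) we run with `K = 20`: at `K = 60` the kNN neighborhoods are
dominated by the ~50 noise dimensions and community detection degrades,
while `K = 20` retains the full informative structure.  This is a
property of the equal-weight coordinate convention, not of the data size
per se.

## Graph clustering

A directed kNN graph (Euclidean distance in `Φ`-space) is symmetrized and
each edge reweighted by the Jaccard similarity of the endpoints'
neighborhoods; a neighborhood is the point itself plus its k nearest
neighbors, and distance ties are broken by point index so the graph is
fully deterministic.  `k = max(round(0.01 n), 10)`: one percent of cells,
floored so small inputs retain meaningful neighborhoods.  Leiden community
detection optimizes resolution-parameterized modularity (the
RBConfiguration quality function — the partition type is our choice, as
modularity is the conventional default) once per resolution on the ladder
0.5, 0.6, …, 1.4.  Runs that collapse to a single cluster cannot support
a max/min rank ratio and are skipped with a warning; their cluster counts
are likewise excluded from the null.

## The rank log-ratio statistic

Per run: cluster centroids are means of member-cell coordinates; genes are
ranked (1 = closest, ties by gene index, so each cluster's ranking is a
strict permutation of 1..p) by Euclidean distance to each centroid; the
per-gene statistic is `v = ln(max rank / min rank)` (natural log — the
reference values 6.56 = ln(12045/17), 7.6 = ln(10000/5),
0.15 = ln(14000/12000), 1.4 = ln(800/200) pin the base).  Across runs the
statistics are summed.  Top-γ selection (when a gene budget is known) uses
the same summed statistic, avoiding a second code path.

## The order-statistic null

Under the null a gene's d ranks are i.i.d. discrete-uniform on 1..p.  The
joint law of their minimum k₁ and maximum k₂ is, for k₁ < k₂,

    ((k₂−k₁+1)/p)^d + ((k₂−k₁−1)/p)^d − 2((k₂−k₁)/p)^d

and `(1/p)^d` on the diagonal k₁ = k₂ (the all-draws-equal atom; the
k₁ < k₂ expression does not specialize to the diagonal — evaluating it
there would double-count for d ≥ 2 and break normalization, which the
exhaustive-enumeration tests confirm).  The pmf of `V = ln(k₂/k₁)`
aggregates pairs with equal *reduced-fraction* ratio (never compared as
floats); its support size is `1 + Σ_{b=2..p} φ(b)` by a totient sieve
(68,394,316 distinct values at p = 15,000, out of p(p+1)/2 = 112,507,500
pairs).  Exact enumeration is capped at 5×10⁶ pairs; beyond that the
caller is directed to Monte-Carlo mode, which is also how the multi-run
sum `Σₜ vₜ` (one independent V per run, each with its own dₜ) is always
handled: T = 20,000 seeded replicates by default.

P-values are the standard +1-corrected upper-tail estimator
`(1 + #{samples ≥ v}) / (T + 1)`, which cannot return 0 and keeps BH
well-behaved; the smallest attainable value is 1/(T+1) ≈ 5×10⁻⁵ at the
default T.  Genes with p > 0.9 — an over-represented upper atom under the
discrete null — are excluded before Benjamini–Hochberg step-up at
α = 0.05 (their q-value is reported as NA).  No uniform-variate
randomization for discrete BH is applied; at these support sizes the
discreteness is negligible.

## Synthetic benchmark generator

The generator emulates a population-structured benchmark design:
10 populations at abundances 25/20/16/10/8/7/6/4/3/1% of 6,000 cells
(population 1, at 60 cells, is the minority population), 15,000 genes of
which 200 are drivers (20 per population, upregulated in exactly one
population) and 1,800 are DE genes (up- or down-regulated in 2–4
populations — the upper cap of 4 is our identifiability choice), 2,000
informative genes in total.  Twenty-four intensity levels interpolate the
fold-change ranges on an equally spaced open-interval grid
(`lo + (hi−lo)·ℓ/25`), increasing the "up" and decreasing the "down"
parameters with the level so higher levels are easier; "fine" mode spans
a_up ∈ (1.5, 2), b_up ∈ (2, 2.5), a_down ∈ (0.4, 0.6), b_down ∈ (0.6, 0.8)
and "coarse" mode a_up ∈ (2, 3), b_up ∈ (2.5, 3.5), a_down ∈ (0.1, 0.3),
b_down ∈ (0.3, 0.5).  Driver fold changes come from the up-range scaled
by 1.2.

Counts follow a Gamma–Poisson recipe: per-gene baseline rates are
log-normal (median 0.3 counts/cell, log-sd 1.5 — a realistic dynamic
range yielding majority-zero matrices), per-cell library factors are
log-normal (log-sd 0.3, unit median), and `Y ~ Poisson(library ×
baseline × fold change)`.  This reproduces the *structure* the pipeline
and metrics need (populations, planted truth, sparsity, library-size
nuisance); it does not reproduce gene–gene correlation, batch structure,
UMI saturation, or parameters estimated from any real dataset, so passing
benchmarks here demonstrate correct recovery of planted population signal,
not performance on real tissues.  Binomial count splitting
(`Binom(Y, ε)` plus exact remainder) supports consistency experiments.

The scaled benchmark used by the fast end-to-end tests is 1,000 cells ×
2,000 genes with five populations (abundances 30/25/20/15/10%), 20
drivers + 180 DE genes, coarse mode at mid intensity (level 12) — sizes
chosen so a ten-seed study completes in well under a minute while leaving
the selection task non-trivial.

## Evaluation metrics

Jaccard for whole-truth comparison; recall/precision/F1 against a
minority-population truth subset (empty selections score 0 with a
warning); purity, ARI, NMI (2I/(H+H) normalization; defined as 0 with a
warning for single-cluster labelings), mean silhouette, and neighborhood
hit (fraction of each point's 30 nearest embedding neighbors sharing its
label, averaged).  The downstream harness reduces the selected-gene raw
count submatrix to 15 principal components (genes centered by PCA; no log
transform, consistent with the method's raw-count stance) and k-means
with fixed seed.  The neighborhood-hit embedding is a parameter: any
coordinate matrix may be supplied.

## Determinism and degenerate inputs

Every source of randomness (SVD starting vector, Leiden, Monte-Carlo
null, generator, k-means) is seeded from the configuration; identical
inputs and seeds give byte-identical selection tables.  Distance and
statistic ties are broken by index everywhere.  Degenerate cases are
errors with named offenders: constant genes at coding time (unless
dropped first), zero column masses, K out of range, k out of range,
single-cluster-only clusterings, gamma out of range, epsilon outside
(0, 1).

## Known limitations

- No HDF5/.h5ad ingestion; Matrix Market and dense TSV/CSV only.
- Exact pmf evaluation is limited to small p; real-data scales always use
  Monte-Carlo (as intended by the method).
- The independence assumption across clusters in the null is a modeling
  idealization; rejected genes indicate departure from it, which is the
  point, but the p-values are not calibrated for correlated partitions.
- The generator's noise model is deliberately simple (see above).
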