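# mcadet

Feature selection for single-cell RNA-seq count matrices: identify highly
variable genes (HVGs) by combining **multiple correspondence analysis
(MCA)**, **multi-resolution Leiden community detection**, and a
**distance-rank order-statistic test**.

## The problem

scRNA-seq expression matrices are sparse, high-dimensional and noisy; most
downstream analysis (clustering, trajectory inference, annotation) starts
by selecting one to three thousand informative genes.  Dispersion- and
dropout-based selectors struggle on *fine-resolution* data — closely
related cell subtypes, or minority populations of a few dozen cells —
where the informative signal is subtle.  This package targets exactly that
regime and works directly on raw counts: no normalization or log
transform is applied.

## The method

Given a cell × gene count matrix **Y** (n × p):

1. **Fuzzy coding.** Each gene is doubled into "presence"/"absence"
   categories with membership
   `Z⁺ᵢⱼ = (Yᵢⱼ − min_j) / (max_j − min_j)`, `Z⁻ = 1 − Z⁺`, giving an
   n × 2p matrix `Z` on a common [0, 1] scale for every gene.
2. **MCA.** The correspondence matrix `P = Z/(np)` with row masses
   `r = 1/n` and column masses `c` yields standardized Pearson residuals
   `R = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2}`, whose truncated SVD
   (`K` = 60 components by default) produces *standard* cell coordinates
   `Φ = D_r^{-1/2} U` and *principal* gene-category coordinates
   `G = D_c^{-1/2} V Λ` in one shared biplot space, where gene–cell
   proximity means association.
3. **Clustering.** A Jaccard-reweighted kNN graph on `Φ` (k = 1% of
   cells, floor 10) is partitioned by Leiden at resolutions
   0.5, 0.6, …, 1.4 — ten partitions, no "best" resolution chosen.
4. **Rank statistic.** For each partition, genes are ranked by Euclidean
   distance to every cluster centroid; a gene's variability is
   `v = ln(max rank / min rank)` — huge when the gene hugs one cluster and
   shuns another, near 0 for uniformly close (housekeeping) or uniformly
   far (irrelevant) genes.  Statistics are summed across the ten runs.
5. **Testing.** Under the null an uninformative gene's ranks are i.i.d.
   discrete-uniform on 1..p, so `v` follows an exact order-statistic
   distribution `Rdis(p, d)`; the multi-run sum is simulated (T = 20,000
   Monte-Carlo replicates), upper-tail p-values are computed, genes with
   p > 0.9 are set aside, and Benjamini–Hochberg at α = 0.05 selects the
   HVGs.  A `topgamma` mode instead returns the top-γ genes by the summed
   statistic.

The package also ships a synthetic benchmark generator (10 populations,
graded fold-change intensities, driver/DE gene design, binomial count
splitting) and the evaluation metrics (Jaccard, minority-F1, purity, ARI,
NMI, silhouette, neighborhood hit), so everything is testable offline.

## Worked example

```python
import numpy as np
from mcadet import scaled_design, simulate_counts, run_pipeline, RunConfig, jaccard

design = scaled_design(mode="coarse", level=12, seed=1)   # 1,000 cells x 2,000 genes
data = simulate_counts(design)                            # 200 planted informative genes
result = run_pipeline(data.counts, RunConfig(K=20, seed=1))

selected = result.selected_genes
print(f"clusters per resolution: {result.cluster_counts}")
print(f"genes selected: {len(selected)} of {len(result.selection.gene_ids)}")
print(f"Jaccard vs planted truth: {jaccard(data.truth_hvgs, selected):.3f}")
```

prints

```
clusters per resolution: [4, 4, 6, 7, 7, 10, 9, 13, 13, 15]
genes selected: 229 of 2000
Jaccard vs planted truth: 0.375
```

The ten Leiden runs find 4–15 communities as the resolution rises; the
test selects 229 genes, and their overlap with the 200 planted informative
genes (Jaccard 0.375, versus ≈ 0.05 for a random pick of the same size)
shows the rank statistic concentrating on the planted signal.  The three
highest-scoring genes illustrate the statistic's scale — e.g.
`gene_00678` with summed v = 72.2 and Monte-Carlo p = 5.0e-05, the
smallest value attainable at T = 20,000 replicates.

The same pipeline is available from the shell:

```sh
mcadet simulate --outdir data/ --mode coarse --level 12 --seed 1
mcadet run data/matrix.mtx --out selection.tsv --seed 1
mcadet evaluate --selected selected.txt --truth data/truth_hvgs.txt
```

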