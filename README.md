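# mcfuse

A toolkit for the computational stages of joint single-nucleus multi-omic
profiling, where DNA methylation, chromatin accessibility (NOMe-seq) and the
transcriptome are read out of the *same* nuclei. It is aimed at analysts
working with snmC-seq / snmCAT-seq-style data who need the post-alignment
machinery: separating bisulfite reads by molecular origin, turning sparse
methylation counts into clusterable features, calling clusters reproducibly,
and — the part unique to multi-modal data — using one modality to *validate*
and *fuse* clusters defined on another.

## What it computes

**Read partitioning.** In a joint methylome + transcriptome library,
cDNA-derived reads appear almost fully methylated in non-CG (CH) context
while genomic reads show the low somatic background. A read with mCH ratio
< 0.5 and ≥ 3 CH cytosines is classified genomic DNA; a read with mCH ratio
> 0.9 and ≥ 3 cytosines is RNA; everything else is ambiguous
(`mcfuse.read_partition`).

**Beta-binomial methylome normalization.** Per cell, the raw feature rates
mc/cov are shrunk toward a beta prior fitted by the method of moments,

    α = m(m(1−m)/v − 1),  β = (1−m)(m(1−m)/v − 1),

with m, v the mean and variance of the cell's raw rates. The posterior rate
(α + mc)/(α + β + cov) is divided by the prior mean m = α/(α+β), so
zero-coverage features sit exactly at 1 and low-coverage features gravitate
toward 1 (`mcfuse.methylome`). Highly variable features are picked by
dispersion standardized within mean × coverage bins.

**NOMe-seq accessibility.** Per 5 kb bin and cell, GpC methylation counts
are tested against Binomial(cov, global) with the cell's global GmCY level;
bins with P(X ≥ observed) < 0.05 are called open, and the binary matrix is
embedded by latent semantic analysis with log term frequency
(`mcfuse.accessibility`).

**Consensus clustering.** Leiden clustering is repeated with many random
starts on one KNN graph; cells are then re-clustered by outlier-aware DBSCAN
over the label-permutation-safe Hamming distance (fraction of runs
disagreeing on a cell pair). Each consensus version is scored by a
class-balanced classifier under recursive feature elimination, outliers are
rescued at prediction probability > 0.5, and the final resolution is the
largest one keeping outliers < 5%, balanced accuracy > 0.95 and mean
cluster size ≥ 30 (`mcfuse.consensus`).

**Cross-modal validation.** The two modalities are co-embedded by CCA (SVD
of X Yᵀ after column standardization); a cell's *k-partners* are its k
nearest cross-modal neighbors. Per cluster C:

- over-splitting `S_over(C) = 1 − (1/|C|²) Σ_{i∈C} Σ_{j∈P_i(|C|)} 1[C_j = C]`
  — 0 means the cluster keeps its partners to itself;
- under-splitting `S_under(C)` — the slope of the cumulative distribution of
  the normalized self-radius ρ = r/|C| at its lower quartile, where the
  self-radius r_i counts cross-modal profiles closer to cell i than its own
  paired profile; 1 for a homogeneous cluster, > 1 when substructure hides.

Cluster number is cross-validated by clustering one modality and scoring
cell-vs-centroid MSE on the other, with the information criteria
`AIC = MSE + 2dσ²/N` and `BIC = MSE + ln(N)·dσ²/N` (`mcfuse.validation`).

**Data fusion.** Features are smoothed within modality by a row-stochastic
diffusion operator `W = pI + (1−p)A` built from an adaptive Gaussian kernel;
cross-modal matches come from *restricted k-partners*: k rounds of greedy
nearest-eligible matching in which no target cell may serve more than
`k′ = ⌈z·k·N_source/N_target⌉` sources. The missing modality is imputed by
averaging partners' smoothed features and all cells are jointly reduced and
Leiden-clustered; labels can also be transferred by partner majority
(`mcfuse.fusion`).

**mCH–RNA coupling.** Per gene, the Spearman correlation between normalized
gene-body mCH (rate / per-cell global mCH) and log10(TPM+1) expression is
tested against an empirical null built by shuffling the cell correspondence
between modalities, with significance at empirical FDR < 0.05; η² quantifies
the variance fraction explained by cluster identity (`mcfuse.coupling`).

All of it is exercisable without external data through
`mcfuse.synthetic`, which generates clustered, coupled multi-modal datasets
(beta-binomial methylation with per-cell global levels, negative-binomial
RNA, binomial GpC accessibility, read-level mCH mixtures) with ground truth.

## Worked example

```python
import numpy as np
from mcfuse import synthetic, methylome, coupling, validation, fusion

cfg = synthetic.SyntheticConfig(n_cells=300, n_genes=200, n_clusters=3,
                                coupled_fraction=0.5, seed=0)
mc_counts, rna, truth = synthetic.generate_multimodal(cfg)

# beta-binomial normalization
pcm = methylome.PairedCountMatrix(mc_counts.mc, mc_counts.cov)
rates = methylome.normalize_rates(pcm, methylome.fit_priors(pcm))
print(f"normalized rates in [{rates.values.min():.2f}, {rates.values.max():.2f}], "
      f"mean {rates.values.mean():.2f}")

# gene-level mCH--RNA coupling with an empirical shuffled null
mch = coupling.normalize_gene_mch(pcm.mc / np.maximum(pcm.cov, 1), truth.global_mch)
expr = coupling.normalize_expression(rna)
table = coupling.correlate_genes(mch, expr, n_shuffles=50, fdr=0.05, seed=0)
sig = table.loc[table["significant"], "gene"].to_numpy()
print(f"coupled genes called: {len(sig)}")

# cross-modal cluster diagnostics (methylation sign-reversed before CCA)
emb = validation.cca_coembed(mch.max() - mch, expr, n_components=20)
scores = validation.split_scores(emb, truth.cluster_labels)
print("S_over:", np.round(scores.s_over.to_numpy(), 3))
print("S_under:", np.round(scores.s_under.to_numpy(), 2))

# fuse the two modalities over the coupled genes
result = fusion.fuse_datasets(mch[:, sig], expr[:, sig], resolution=0.5, seed=0)
print(f"co-cluster accuracy: {(result.labels_a == result.labels_b).mean():.3f}")
```

Output:

```
normalized rates in [0.12, 6.79], mean 1.00
coupled genes called: 106
S_over: [0.007 0.004 0.006]
S_under: [1.04 0.76 1.24]
co-cluster accuracy: 1.000
```

The normalization centres every cell at 1 by construction. 106 genes are
called mCH–RNA coupled (95 of the 100 planted, plus a few cluster-correlated
bystanders at the 5% FDR). The three true clusters score essentially zero
over-splitting, S_under stays in the homogeneous band around 1, and fusing
methylome against transcriptome over the coupled genes co-clusters both
profiles of every cell.

A CLI mirrors the library (`mcfuse simulate|partition-reads|normalize|
select-features|nome|cluster|fuse|validate|couple`); run `mcfuse --help`.

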