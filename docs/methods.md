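# Methods

This note documents the models, numerical choices and limitations behind
each stage of the toolkit, in the order data flows through it.

## Read-origin classification

A bisulfite-converted cDNA read retains its cytosines (the reverse
transcription happens before conversion is read out), so its apparent
non-CG methylation ratio is near 1, while a genomic read shows the somatic
mCH background of a few percent. Classification uses only two thresholds
and a minimum evidence count: DNA iff mCH/CH < 0.5 with ≥ 3 CH cytosines,
RNA iff mCH/CH > 0.9 with ≥ 3 cytosines; both inequalities are strict, so
reads exactly at a threshold are ambiguous, as are reads with fewer than 3
CH sites or none at all (no division by zero). The gap between 0.5 and 0.9
is deliberate: the cost of misclassifying a genomic read as RNA
(contaminating expression counts) exceeds the cost of discarding it, so the
RNA criterion is much stricter. The canonical input is a TSV of per-read
context counts; SAM input with a Bismark-style XM tag is parsed with pysam,
so the module carries no alignment logic of its own. Parse errors report
the offending symbol and its 1-based position.

## Beta-binomial methylome normalization

Feature-level methylation is a pair of counts (mc, cov). Raw rates mc/cov
are unusable at single-cell coverage, so each cell gets an empirical-Bayes
prior Beta(α, β) fitted by the method of moments from its own covered
features (cov > 0; zero-coverage features carry no rate information):

    α = m(m(1−m)/v − 1),   β = (1−m)(m(1−m)/v − 1).

Cells with noisier raw rates (larger v) receive weaker priors. The
posterior (α + mc)/(α + β + cov) divided by the prior mean m is the working
rate: exactly 1 at zero coverage, near 1 at low coverage, approaching
(mc/cov)/m as coverage grows. The method-of-moments fit requires
0 < v < m(1−m); v at or beyond that bound (or numerically zero, below
1e−12) raises a degenerate-prior error rather than silently producing a
non-positive α. Priors are fitted after feature filtering, so removed bins
do not influence the prior.

Cell QC uses five mapping metrics with defaults mCCC < 0.03 (an upper bound
on bisulfite non-conversion), global mCG > 0.5, global mCH < 0.2, total
reads > 500,000, mapping rate > 0.5. Bin filtering keeps features with mean
coverage in [300, 3000] (preset (250, 2500) for the shallower joint assay)
and no base-pair overlap with a blacklist BED (0-based half-open
coordinates throughout).

### Variable-feature selection

Both the mean rate and the mean coverage of a feature shape its dispersion
(variance/mean), so features are grouped on a 20 × 5 quantile grid of
(mean rate, mean coverage) and the dispersion is standardized within each
group. Two deliberate choices: the grid uses quantile edges so occupancy
stays even and no feature is stranded in a sparse outer bin, and the
standardization is median/MAD rather than mean/SD — a handful of genuinely
variable features inside a bin would otherwise inflate the bin's own scale
and mask themselves. Singleton groups score 0. The top 3000 features by
normalized dispersion are kept by default, ties broken by ascending index.
Downstream embedding z-scores the selected features and takes a fixed,
explicitly configured number of principal components (default 20) — the
variance-ratio elbow is a judgement call, so the component count is an
input, not an automatic decision.

## NOMe-seq accessibility

Exogenous GpC methyltransferase marks accessible DNA; the signal is the
GmCY basecall count of a bin against the cell's global GmCY level. The null
is Binomial(cov, global) and the tail is inclusive — P(X ≥ observed),
implemented as the survival function at observed − 1 — because the event
"equal or greater than observed" is what the test asks; an exclusive tail
would mis-handle the discrete boundary. Bins with p < 0.05 are 1, others
(and zero-coverage bins) 0. Global rates of exactly 0 or 1 are rejected.

The LSA embedding filters bins open in ≤ 10 cells, then removes bins whose
z-scored column sum (computed on the post-filter matrix) is ≥ 2, row
normalizes, applies C = log(B + 1) · log(1 + N/colsum), and truncates the
SVD at 15 components. Left singular vectors are returned unscaled by
default (σ-scaling is a flag); each vector's largest-magnitude element is
made positive so runs are bitwise reproducible. Cells left with no open
bins are dropped with a warning and flagged in the returned mask. The
min-cells filter precedes the column-sum filter; the order is a choice.

## Consensus clustering

Leiden on a KNN graph (default k = 25, configurable) is repeated n_runs
times (default 200) with seeds seed..seed+n_runs−1 on one shared graph. The
consensus distance between two cells is the fraction of runs assigning them
different labels — invariant under per-run label permutation and a
pseudometric in [0, 1]. DBSCAN (min_samples 5) over this distance is swept
across 50 epsilon values in (0, 1]; one version per distinct cluster count
is kept (fewest outliers wins), covering the count range seen across runs.

The supervised evaluation contract is: class-imbalance-aware multiclass
classifier, recursive feature (component) elimination under cross-validated
balanced accuracy, 90/10 train/holdout split with outliers excluded. The
implementation uses a random forest with balanced subsampled class weights
inside scikit-learn's RFECV; any classifier meeting the contract would do.
Clusters smaller than the fold count shrink the fold count with a warning.
The fitted model rescues outliers whose top predicted class exceeds
probability 0.5. Resolution selection takes the largest resolution whose
best version has outlier fraction < 0.05, holdout balanced accuracy > 0.95
and mean cluster size ≥ 30; failure lists every criterion's violators.

Markers are one-vs-rest rank-sum tests with Benjamini–Hochberg correction:
RNA markers need adjusted p < 0.01, log2 fold-change > 1, AUROC > 0.8;
methylation markers use the reversed direction (hypomethylation), delta
(cluster mean − mean of the other clusters' means) < −0.3 and AUROC > 0.8
for the "lower" orientation. Clusters with fewer than 10 markers are merged
into the cluster with the nearest centroid (Euclidean, in the clustering
embedding; ties to the larger cluster) and markers are recomputed until all
clusters qualify or one remains. Note that one-vs-rest markers only vanish
for a split cluster when its twin makes up a large share of the "rest"; the
merge criterion targets clusters with no distinguishing genes, not every
conceivable split.

## Cross-modal validation

The co-embedding is the SVD of X Yᵀ with columns standardized per modality
(zero-variance columns dropped from both) — equivalent to a CCA between the
two cell sets. Two numerical choices matter:

- **Orientation.** A modality anti-correlated with the other (gene-body mCH
  vs expression) must be sign-reversed (max − X) before co-embedding;
  otherwise U ≈ −V and every cell lands opposite its own partner profile.
  The fusion pipeline applies the reversal internally; validation callers
  reverse explicitly.
- **Scaling.** Coordinates are scaled by the singular values by default.
  Orthonormal singular vectors weight every component equally, which lets
  components carrying no cross-modal covariance dominate Euclidean
  distances on low-rank data; σ-scaling makes distance reflect shared
  structure. A flag restores unscaled vectors.

Partner lists sort by distance with ties broken by ascending index
(numpy's stable argsort). S_over uses per-cell k equal to the cluster size
(capped at the number of cells); a singleton cluster uses k = 1. The
self-radius r_i counts strictly closer cross-modal profiles, so identical
profiles give r = 0. S_under divides the within-cluster CDF of ρ = r/|C| at
the 0.25 quantile by 0.25 — the slope of the cumulative distribution at the
lower quartile, 1 for a uniform (homogeneous) cluster. The ideal reference
shuffles each gene column independently within each cluster and modality,
preserving per-gene cluster marginals exactly while destroying per-cell
pairing.

Cross-validated cluster-number selection clusters the top 20 PCs of one
modality (Leiden, one seeded run per replicate) and scores cell-vs-centroid
MSE of the other modality over random folds (default 5 seeds × 5 folds; a
10 × 3 variant is available by argument). Test cells in clusters absent
from the training fold fall back to the global training mean. The
information criteria under a Gaussian centroid model are
AIC = MSE + 2dσ²/N and BIC = MSE + ln(N)·dσ²/N with σ² the mean per-feature
variance of the evaluation modality (single-cluster assumption) unless
supplied; for N > e² the BIC penalty is heavier, so on a convex curve its
optimum is at most the AIC's.

Fusion quality metrics index both modalities' rows (2N) in one structure:
the rank of a cell's partner row among all other rows (1-based, own row
excluded) normalized by 2N; cells above 0.3 count as mis-fused. Co-clusters
come from Leiden with the resolution bisected geometrically (20 iterations)
to hit a target count, accepting the nearest achievable count with a
warning. The overlap score between two clusterings through a joint
co-clustering is Σ_g min(|a∩g|/|a|, |b∩g|/|b|) ∈ [0, 1].

## Data fusion

Within-modality smoothing builds an adaptive Gaussian kernel on the kNN
graph (k = 30, σ_i = distance to the ka = 5-th neighbor), zeroes the
diagonal, symmetrizes by addition, row-normalizes and mixes with the
identity: W = pI + (1−p)A, keeping p = 0.9 of each methylation profile and
p = 0.7 of each RNA profile (RNA is noisier per cell, so it borrows more
from neighbors). Duplicate points (σ = 0) fall back to the smallest
positive neighbor distance with a warning.

Restricted k-partners runs k rounds; each round visits sources in a fresh
seeded random order and links each to its nearest eligible target not
already among its partners, retiring targets at capacity
k′ = ⌈z·k·N_s/N_t⌉. With z = 1 every target ends at k′ or k′ − 1. The
implementation advances a per-source pointer down the precomputed distance
ranking (lazily extended neighbor lists); its behavior is pinned to a
brute-force full-rescan oracle in the tests. Distance ties break by
ascending target index. In the degenerate case where every remaining
eligible target is already a partner of the source, distinctness is relaxed
for that single pick with a warning. Both Euclidean and 1 − Spearman
metrics are supported (the latter used when matching methylation against
ATAC-style signals).

The full fusion pipeline: sign-reverse methylation, smooth each modality on
its own 50-PC space, co-embed by CCA (50 components), match by RKP, impute
the missing modality as the unweighted partner mean, PCA (top 50) on the
stacked measured + imputed features, then KNN + Leiden (and optionally
UMAP, n_neighbors 30, min_dist 0.5). The imputation direction defaults to
imputing the smaller dataset into the larger. The feature set is the
caller's choice; the natural defaults are genes significantly coupled at
empirical FDR < 0.05, or a top-N by |correlation|. The current co-embedding
step requires the two cell sets to be equal-sized (the toolkit's paired
assay setting); for unequal sets the RKP/impute/transfer machinery is
usable directly on any common embedding. Label transfer gives a source cell
the label carried by ≥ half of its partners, else UNASSIGNED; exact-ties
resolve toward the label with more partners graph-wide, then
lexicographically.

## mCH–RNA coupling

Expression is log10(TPM + 1) (equal gene lengths reduce TPM to CPM — the
synthetic data uses this); gene-body mCH is the raw rate divided by the
cell's global mCH. Genes must be expressed in > 1% of cells and covered
(> 20 basecalls) in > 95% of cells. Per-gene Spearman rho is computed by
ranking once per modality; the null permutes the cell correspondence
between modalities (one shared permutation per shuffle, preserving
within-modality gene–gene structure — ranks permute with cells, so each
shuffle is a cheap row permutation of the precomputed ranks). The empirical
FDR at cutoff t for the negative direction is (mean null count of genes
with ρ ≤ t)/(observed count with ρ ≤ t); the significant set lies beyond
the least extreme cutoff with FDR below target, which makes the calls
nested across FDR levels by construction. One-sided negative is the
default; positive and two-sided modes exist. Constant genes are flagged and
excluded. η² = SS_between/SS_total per gene with size-weighted cluster
means; zero-variance genes report 0 with a flag.

A caveat the synthetic tests make visible: genes whose methylation and
expression both vary across the *same* cluster structure acquire nonzero
correlations even without gene-level coupling, and the shuffled null (which
destroys the cluster alignment) counts them as signal. The same is true of
any cluster-shuffled empirical null on real data; "coupled at FDR < 0.05"
means coupled relative to scrambled cells, not conditionally on cell type.

## Synthetic data

The generator emulates: discrete cell types (near-equal occupancy); RNA
counts negative-binomial (gamma–Poisson, dispersion 0.5) around
cluster-specific log-normal means with per-cell log-normal size factors;
per-cell global mCH uniform in (0.02, 0.06) — the adult-neuron range;
methylation counts beta-binomial (concentration 100) around
global × gene-by-cluster enrichment, with enrichment factors renormalized
to mean 1 per cluster so each cell's marginal methylation matches its
global level; for coupled genes (default 20%) the enrichment is a
decreasing logistic in standardized log expression spanning [0.2, 3.0]
(bounded, as methylation fractions must be), giving median per-gene
Spearman ρ < −0.3 at defaults; per-gene coverage Poisson(100). NOMe counts
are binomial with per-cell global GpC levels uniform in (0.15, 0.35) and
cluster-private open bins at 2.5 × global (capped at 0.95). Reads draw
their mCH ratio from Beta(50, 1) (RNA) or Beta(2, 48) (DNA) with
Poisson(25) CH cytosines per read — roughly the CH density of a 100–150 bp
read — placing the mixture safely on either side of the 0.5/0.9 thresholds;
a "hard" mode (Beta(12, 3) vs Beta(6, 10)) narrows the gap to stress the
classifier.

What the generator does **not** emulate: doublets, batch or plate effects,
coverage heteroskedasticity along the genome, bisulfite non-conversion,
gradient (non-discrete) cell populations, and gene–gene correlation beyond
cluster structure. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative assumptions, not robustness to every
artefact of real libraries.

## Problem sizes and determinism

Tests and the acceptance script run at a few hundred cells and genes —
enough for every score to reach its analytic regime (S_over ≈ 0 on
separated clusters, S_under ≈ 1 on shuffled references, exact capacity
bounds) while keeping the whole suite in the order of a minute. All
stochastic stages take explicit integer seeds: Leiden seeds are
seed..seed+n_runs−1, RKP visit orders and all generators use
numpy's PCG64 via `default_rng(seed)`, and SVD sign conventions are fixed,
so equal inputs and seeds reproduce results bitwise.
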