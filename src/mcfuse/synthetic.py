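"""Synthetic multi-modal single-cell data with known ground truth.

The generator emulates the statistical structure of joint single-nucleus
methylome + transcriptome (+ NOMe-seq accessibility) data:

- cells belong to a small number of discrete types (clusters);
- RNA counts are negative-binomial with cluster-specific log-normal means;
- gene-body non-CG methylation (mCH) counts are beta-binomial around a
  per-cell global mCH level times a gene-by-cluster enrichment factor;
- for a "coupled" subset of genes the methylation enrichment is a decreasing
  logistic transform of the standardized log expression, reproducing the
  anti-correlation of gene-body mCH and expression seen in neurons;
- GpC accessibility counts are binomial, with cluster-specific open bins
  elevated above the per-cell global GpC methylation level;
- bisulfite reads are mixtures of RNA-origin (near-fully C->T converted,
  i.e. apparent mCH ratio near 1) and DNA-origin (mCH ratio near the
  genomic background) reads.

All randomness flows through a single integer seed; identical configs and
seeds give bitwise-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .read_partition import ReadMethylationRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_multimodal",
    "generate_reads",
    "generate_nome_counts",
    "perturb_labels",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the multi-modal generator.

    Defaults are sized for desk-scale runs while keeping the effect sizes
    (cluster separation, coupling strength, coverage) in the regime typical
    of adult-brain single-nucleus data: per-cell global mCH of a few percent,
    ~100 cytosine basecalls per gene body, strongly overdispersed RNA counts.
    """

    n_cells: int = 500
    n_genes: int = 300
    n_clusters: int = 3
    coupled_fraction: float = 0.2
    rna_dispersion: float = 0.5
    meth_concentration: float = 100.0
    coverage_mean: float = 100.0
    global_mch_range: tuple[float, float] = (0.02, 0.06)
    seed: int = 0
    # effect sizes
    cluster_logfc_sd: float = 1.0       # sd of per-cluster log-mean RNA shifts
    uncoupled_meth_sd: float = 0.3      # sd of log enrichment for uncoupled genes
    coupling_slope: float = 3.0         # steepness of the logistic coupling
    coupling_range: tuple[float, float] = (0.2, 3.0)  # mCH enrichment bounds
    rna_mean_scale: float = 5.0         # overall RNA counts-per-gene scale

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_genes, self.n_clusters) < 1:
            raise ValueError("n_cells, n_genes and n_clusters must be >= 1")
        if not 0.0 <= self.coupled_fraction <= 1.0:
            raise ValueError(f"coupled_fraction must be in [0, 1], got {self.coupled_fraction}")
        if self.rna_dispersion <= 0 or self.meth_concentration <= 0 or self.coverage_mean <= 0:
            raise ValueError("dispersion, concentration and coverage_mean must be positive")
        lo, hi = self.global_mch_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"global_mch_range must lie inside (0, 1), got {self.global_mch_range}")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    cluster_labels: np.ndarray          # (n_cells,) int
    coupled_genes: np.ndarray           # sorted gene indices
    rna_means: np.ndarray               # (n_genes, n_clusters) expected counts
    meth_levels: np.ndarray             # (n_genes, n_clusters) fractions in [0, 1]
    global_mch: np.ndarray              # (n_cells,) per-cell global mCH


@dataclass
class PairedCounts:
    """Lightweight (mc, cov) pair; the full container lives in mcfuse.methylome."""

    mc: np.ndarray
    cov: np.ndarray
    context: str = "HCH"


def _even_labels(n_cells: int, n_clusters: int, rng: np.random.Generator) -> np.ndarray:
    """Assign cells to clusters as evenly as possible, in shuffled order."""
    base = np.repeat(np.arange(n_clusters), n_cells // n_clusters)
    extra = np.arange(n_cells - base.size) % n_clusters
    labels = np.concatenate([base, extra]).astype(np.int64)
    rng.shuffle(labels)
    return labels


def generate_multimodal(config: SyntheticConfig):
    """Generate paired methylome and transcriptome matrices with ground truth.

    Returns
    -------
    (mc_counts, rna_counts, truth)
        ``mc_counts`` is a :class:`PairedCounts` with ``mc``/``cov`` integer
        matrices (cells x genes), ``rna_counts`` is a cells x genes integer
        matrix, and ``truth`` a :class:`SyntheticTruth`.
    """
    rng = np.random.default_rng(config.seed)
    n, g, k = config.n_cells, config.n_genes, config.n_clusters

    labels = _even_labels(n, k, rng)

    n_coupled = int(round(config.coupled_fraction * g))
    coupled = np.sort(rng.choice(g, size=n_coupled, replace=False))
    coupled_mask = np.zeros(g, dtype=bool)
    coupled_mask[coupled] = True

    # RNA: per-gene baseline log-mean plus cluster-specific shifts
    base_log = rng.normal(0.0, 1.0, size=g)
    shifts = rng.normal(0.0, config.cluster_logfc_sd, size=(g, k))
    log_mu = base_log[:, None] + shifts
    mu = np.exp(log_mu)
    mu *= config.rna_mean_scale / mu.mean()

    # Methylation enrichment factor per gene x cluster, centred at 1 per cluster.
    z = (log_mu - log_mu.mean(axis=1, keepdims=True)) / (
        log_mu.std(axis=1, keepdims=True) + 1e-12
    )
    lo, hi = config.coupling_range
    f_coupled = lo + (hi - lo) / (1.0 + np.exp(config.coupling_slope * z))
    f_uncoupled = np.exp(rng.normal(0.0, config.uncoupled_meth_sd, size=(g, k)))
    factors = np.where(coupled_mask[:, None], f_coupled, f_uncoupled)
    # renormalize so the marginal methylation of a cell matches its global level
    factors = factors / factors.mean(axis=0, keepdims=True)

    g_lo, g_hi = config.global_mch_range
    global_mch = rng.uniform(g_lo, g_hi, size=n)

    p_true = np.clip(global_mch[:, None] * factors[:, labels].T, 1e-4, 0.999)

    cov = rng.poisson(config.coverage_mean, size=(n, g))
    conc = config.meth_concentration
    p_bb = rng.beta(np.maximum(p_true * conc, 1e-8), np.maximum((1.0 - p_true) * conc, 1e-8))
    mc = rng.binomial(cov, p_bb)

    size_factors = np.exp(rng.normal(0.0, 0.3, size=n))
    mean_rna = size_factors[:, None] * mu[:, labels].T
    shape = 1.0 / config.rna_dispersion
    lam = rng.gamma(shape, mean_rna / shape)
    rna = rng.poisson(lam)

    truth = SyntheticTruth(
        cluster_labels=labels,
        coupled_genes=coupled,
        rna_means=mu,
        meth_levels=np.clip(factors * global_mch.mean(), 0.0, 1.0),
        global_mch=global_mch,
    )
    return PairedCounts(mc=mc, cov=cov, context="HCH"), rna, truth


def generate_reads(
    n_reads: int,
    rna_fraction: float,
    seed: int,
    cytosines_mean: float = 25.0,
    hard: bool = False,
):
    """Simulate per-read methylation call counts for an RNA/DNA read mixture.

    RNA-origin reads (cDNA, unmethylated C converted during library prep is
    absent, so CH positions read as methylated) draw their apparent mCH ratio
    from Beta(50, 1); DNA-origin reads from Beta(2, 48), i.e. near the
    genomic non-CG background. ``hard=True`` narrows the gap (Beta(12, 3) vs
    Beta(6, 10)) to stress classification near the 0.5/0.9 thresholds.
    The number of CH cytosines per read is Poisson(``cytosines_mean``).

    Returns
    -------
    (records, origins)
        ``records`` is a list of :class:`ReadMethylationRecord`; ``origins``
        an array of "RNA"/"DNA" ground-truth labels of the same length.
    """
    if not 0.0 <= rna_fraction <= 1.0:
        raise ValueError(f"rna_fraction must be in [0, 1], got {rna_fraction}")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    if n_reads == 0:
        return [], np.array([], dtype=object)

    is_rna = rng.random(n_reads) < rna_fraction
    if hard:
        a_rna, b_rna, a_dna, b_dna = 12.0, 3.0, 6.0, 10.0
    else:
        a_rna, b_rna, a_dna, b_dna = 50.0, 1.0, 2.0, 48.0
    ratio = np.where(is_rna, rng.beta(a_rna, b_rna, n_reads), rng.beta(a_dna, b_dna, n_reads))

    ch = rng.poisson(cytosines_mean, size=n_reads)
    mch = rng.binomial(ch, ratio)
    cg = rng.poisson(2.0, size=n_reads)
    # CpG sites: mostly methylated on genomic DNA, fully "methylated" on cDNA
    mcg = rng.binomial(cg, np.where(is_rna, ratio, 0.8))

    records = [
        ReadMethylationRecord(
            read_id=f"read_{i}", mch=int(mch[i]), ch=int(ch[i]), mcg=int(mcg[i]), cg=int(cg[i])
        )
        for i in range(n_reads)
    ]
    origins = np.where(is_rna, "RNA", "DNA").astype(object)
    return records, origins


def generate_nome_counts(
    config: SyntheticConfig,
    open_bins_per_cluster: int,
    gcy_global_range: tuple[float, float] = (0.15, 0.35),
    open_rate_factor: float = 2.5,
):
    """Simulate NOMe-seq GpC methylation counts over genomic bins.

    Each cluster receives ``open_bins_per_cluster`` private open bins whose
    GmCY rate is ``open_rate_factor`` times the cell's global GpC rate
    (clipped to 0.95); all other bins sit at the global rate. With
    ``open_rate_factor=1`` the signal is degenerate and downstream
    binarization should behave like its type-I error rate.

    Returns
    -------
    (gmcy, gcy_cov, truth)
        counts matrices (cells x bins) and a dict with ``labels``,
        ``global_rates`` and ``open_bins`` (cluster -> bin index array).
    """
    n, n_bins, k = config.n_cells, config.n_genes, config.n_clusters
    if open_bins_per_cluster * k > n_bins:
        raise ValueError("open_bins_per_cluster * n_clusters exceeds the number of bins")
    rng = np.random.default_rng(config.seed)
    labels = _even_labels(n, k, rng)
    global_rates = rng.uniform(*gcy_global_range, size=n)

    perm = rng.permutation(n_bins)
    open_bins = {c: np.sort(perm[c * open_bins_per_cluster : (c + 1) * open_bins_per_cluster]) for c in range(k)}

    rates = np.repeat(global_rates[:, None], n_bins, axis=1)
    for c in range(k):
        cells = labels == c
        rates[np.ix_(cells, open_bins[c])] = np.clip(
            global_rates[cells, None] * open_rate_factor, 0.0, 0.95
        )
    cov = rng.poisson(config.coverage_mean, size=(n, n_bins))
    gmcy = rng.binomial(cov, rates)
    truth = {"labels": labels, "global_rates": global_rates, "open_bins": open_bins}
    return gmcy, cov, truth


def perturb_labels(labels: np.ndarray, mode: str, seed: int = 0) -> np.ndarray:
    """Perturb a clustering for validation fixtures.

    ``split`` randomly halves one cluster (the largest) into two new labels;
    ``merge`` unions the two largest distinct clusters; ``identity`` returns
    a copy of the input.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    if mode == "identity":
        return labels.copy()
    rng = np.random.default_rng(seed)
    out = labels.astype(str).astype(object)
    uniq, counts = np.unique(labels, return_counts=True)
    if mode == "split":
        target = uniq[np.argmax(counts)]
        idx = np.flatnonzero(labels == target)
        half = rng.permutation(idx)[: idx.size // 2]
        out[idx] = f"{target}_a"
        out[half] = f"{target}_b"
        return out
    if mode == "merge":
        if uniq.size < 2:
            raise ValueError("merge requires at least 2 clusters")
        order = np.argsort(counts)[::-1]
        a, b = uniq[order[0]], uniq[order[1]]
        out[(labels == a) | (labels == b)] = f"{a}+{b}"
        return out
    raise ValueError(f"unknown mode {mode!r}; expected split, merge or identity")
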