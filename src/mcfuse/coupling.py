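"""Gene-level coupling of gene-body mCH and RNA expression.

In neurons, gene-body non-CG methylation is anti-correlated with expression
for a large subset of genes. Per gene, the Spearman correlation between
normalized mCH (gene rate divided by the cell's global mCH) and log
expression (log10(TPM+1)) is computed across cells; significance is called
against an empirical null built by shuffling the cell correspondence
between the two modalities, with a global-cutoff empirical FDR.
Cross-cluster variance fractions (eta squared) quantify how much of a
gene's signal is explained by cell type in each modality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_genes_for_correlation",
    "normalize_expression",
    "normalize_gene_mch",
    "correlate_genes",
    "eta_squared",
]


def filter_genes_for_correlation(
    rna_counts: np.ndarray,
    mch_cov: np.ndarray,
    min_expr_cell_fraction: float = 0.01,
    min_cov: float = 20,
    min_cov_cell_fraction: float = 0.95,
) -> np.ndarray:
    """Keep genes expressed in > 1% of cells and covered (> 20 basecalls)
    in > 95% of cells (defaults)."""
    rna = np.asarray(rna_counts)
    cov = np.asarray(mch_cov)
    if rna.shape != cov.shape:
        raise ValueError("rna_counts and mch_cov must be aligned cell-by-gene matrices")
    expressed = (rna > 0).mean(axis=0) > min_expr_cell_fraction
    covered = (cov > min_cov).mean(axis=0) > min_cov_cell_fraction
    return expressed & covered


def normalize_expression(
    counts: np.ndarray, gene_lengths: np.ndarray | None = None
) -> np.ndarray:
    """log10(TPM + 1) expression.

    Without gene lengths, all genes are treated as equal length, making TPM
    proportional to CPM. Cells with zero total counts are dropped (their
    rows are removed) with a warning.
    """
    counts = np.asarray(counts, float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if gene_lengths is not None:
        rate = counts / np.asarray(gene_lengths, float)[None, :]
    else:
        rate = counts
    totals = rate.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} cells with zero total counts", stacklevel=2)
        rate, totals = rate[~empty], totals[~empty]
    tpm = rate / totals[:, None] * 1e6
    return np.log10(tpm + 1.0)


def normalize_gene_mch(mch_rates: np.ndarray, global_mch: np.ndarray) -> np.ndarray:
    """Divide each cell's gene-body mCH rates by its global mCH level."""
    global_mch = np.asarray(global_mch, float)
    if (global_mch <= 0).any():
        raise ValueError("global mCH must be positive for every cell")
    return np.asarray(mch_rates, float) / global_mch[:, None]


def _columnwise_spearman(rank_x: np.ndarray, rank_y: np.ndarray) -> np.ndarray:
    """Pearson correlation of matched pre-ranked columns."""
    x = rank_x - rank_x.mean(axis=0)
    y = rank_y - rank_y.mean(axis=0)
    denom = np.sqrt((x**2).sum(axis=0) * (y**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (x * y).sum(axis=0) / denom


def correlate_genes(
    mch_norm: np.ndarray,
    expr: np.ndarray,
    n_shuffles: int = 100,
    fdr: float = 0.05,
    direction: str = "negative",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene Spearman rho with an empirical shuffled null and FDR calls.

    The null is built by permuting the cell correspondence between modalities
    ``n_shuffles`` times (one shared permutation per shuffle, preserving
    within-modality gene-gene structure). For the negative direction, the
    empirical FDR at a cutoff t is the mean null count of genes with
    rho <= t divided by the observed count; the significant set contains the
    genes beyond the least extreme cutoff with FDR below the target.
    Constant genes have undefined rho and are flagged and excluded.
    """
    if direction not in {"negative", "positive", "both"}:
        raise ValueError(f"unknown direction {direction!r}")
    M = np.asarray(mch_norm, float)
    E = np.asarray(expr, float)
    if M.shape != E.shape:
        raise ValueError("matrices must be aligned cell-by-gene")
    n_cells, n_genes = M.shape
    if n_cells < 3:
        raise ValueError("need at least 3 cells")

    valid = (M.std(axis=0) > 1e-12) & (E.std(axis=0) > 1e-12)
    if not valid.all():
        warnings.warn(
            f"excluding {int((~valid).sum())} constant genes from correlation", stacklevel=2
        )
    rank_m = stats.rankdata(M, axis=0)
    rank_e = stats.rankdata(E, axis=0)
    rho = np.full(n_genes, np.nan)
    rho[valid] = _columnwise_spearman(rank_m[:, valid], rank_e[:, valid])

    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, int(valid.sum())))
    for s in range(n_shuffles):
        perm = rng.permutation(n_cells)
        null[s] = _columnwise_spearman(rank_m[perm][:, valid], rank_e[:, valid])

    obs = rho[valid]

    def _tail_fdr(sign: int) -> tuple[np.ndarray, np.ndarray]:
        """Empirical FDR and per-gene significance for one tail (sign=-1: rho<=t)."""
        v = sign * obs          # larger = more extreme in the chosen tail
        vn = sign * null
        cutoffs = np.sort(np.unique(v))[::-1]
        obs_counts = (v[None, :] >= cutoffs[:, None]).sum(axis=1)
        null_counts = np.array([(vn >= t).sum(axis=1).mean() for t in cutoffs])
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr_curve = null_counts / obs_counts
        ok = np.flatnonzero(fdr_curve < fdr)
        if ok.size == 0:
            return np.full(v.size, np.nan), np.zeros(v.size, dtype=bool)
        # least extreme qualifying cutoff: everything at or beyond it is called
        t_star = cutoffs[ok.max()]
        sig = v >= t_star
        # per-gene empirical FDR at its own value, for reporting
        order = np.searchsorted(-cutoffs, -v)
        per_gene = fdr_curve[np.clip(order, 0, cutoffs.size - 1)]
        return per_gene, sig

    per_gene_fdr = np.full(n_genes, np.nan)
    significant = np.zeros(n_genes, dtype=bool)
    sign_label = np.full(n_genes, "", dtype=object)
    if direction in {"negative", "both"}:
        f_neg, s_neg = _tail_fdr(-1)
        per_gene_fdr[valid] = f_neg
        significant[valid] |= s_neg
        sign_label[np.flatnonzero(valid)[s_neg]] = "negative"
    if direction in {"positive", "both"}:
        f_pos, s_pos = _tail_fdr(+1)
        if direction == "positive":
            per_gene_fdr[valid] = f_pos
        significant[valid] |= s_pos
        sign_label[np.flatnonzero(valid)[s_pos]] = "positive"

    return pd.DataFrame(
        dict(
            gene=np.arange(n_genes),
            rho=rho,
            empirical_fdr=per_gene_fdr,
            significant=significant,
            direction=sign_label,
            valid=valid,
        )
    )


def eta_squared(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Fraction of each gene's variance explained by cluster identity.

    eta^2 = SS_between / SS_total with SS_between over size-weighted cluster
    means. Genes with zero total variance report 0 with a flag.
    """
    X = np.asarray(values, float)
    labels = np.asarray(labels)
    clusters, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    if clusters.size < 2:
        raise ValueError("eta squared requires >= 2 clusters")
    if (counts < 2).any():
        raise ValueError("every cluster needs >= 2 cells")
    grand = X.mean(axis=0)
    ss_total = ((X - grand) ** 2).sum(axis=0)
    ss_between = np.zeros_like(grand)
    for ci, size in enumerate(counts):
        mean_c = X[inverse == ci].mean(axis=0)
        ss_between += size * (mean_c - grand) ** 2
    zero_var = ss_total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        eta2 = np.where(zero_var, 0.0, ss_between / np.where(zero_var, 1.0, ss_total))
    return pd.DataFrame(dict(gene=np.arange(X.shape[1]), eta_squared=eta2, zero_variance=zero_var))
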