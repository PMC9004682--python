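"""NOMe-seq chromatin accessibility: binomial binarization and LSA embedding.

Exogenous GpC methyltransferase marks accessible chromatin, so the GmCY
basecalls of a genomic bin in a cell are modelled as Binomial(cov, global)
with ``global`` the cell's genome-wide GmCY level. A bin is called open (1)
when the probability of observing *equal or greater* GmCY counts under that
null is below a threshold (default 0.05); the inclusive tail is the survival
function evaluated at observed - 1. The resulting binary matrix is embedded
by latent semantic analysis with log term frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

__all__ = [
    "BinaryAccessibilityMatrix",
    "LSAEmbedding",
    "binarize_accessibility",
    "log_tf_idf",
    "lsa_embed",
]


@dataclass
class BinaryAccessibilityMatrix:
    """Cell-by-bin open-chromatin calls (0/1) with per-cell global GmCY rates."""

    values: np.ndarray
    global_rates: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary matrix may contain only 0/1")


def binarize_accessibility(
    gmcy: np.ndarray,
    gcy_cov: np.ndarray,
    global_rates: np.ndarray,
    p_threshold: float = 0.05,
) -> BinaryAccessibilityMatrix:
    """Call bins open where GmCY counts exceed the per-cell binomial null.

    Zero-coverage bins are closed by construction (P(X >= 0) = 1).
    """
    gmcy = np.asarray(gmcy)
    cov = np.asarray(gcy_cov)
    rates = np.asarray(global_rates, dtype=float)
    if np.any(gmcy > cov):
        raise ValueError("gmcy must be <= gcy_cov element-wise")
    if np.any((rates <= 0) | (rates >= 1)):
        raise ValueError("global rates must lie strictly inside (0, 1)")
    # inclusive upper tail: P(X >= obs) = sf(obs - 1)
    pvals = stats.binom.sf(gmcy - 1, cov, rates[:, None])
    values = (pvals < p_threshold).astype(np.int8)
    values[cov == 0] = 0
    return BinaryAccessibilityMatrix(values=values, global_rates=rates)


def log_tf_idf(A: np.ndarray, n_cells: int) -> np.ndarray:
    """Log term frequency times inverse document frequency.

    Rows of A are normalized by their sums (term frequency B), then
    C_ij = log(B_ij + 1) * log(1 + n_cells / colsum_j(A)). A bin open in
    every cell has IDF factor log 2.
    """
    A = np.asarray(A, float)
    B = A / A.sum(axis=1, keepdims=True)
    idf = np.log(1.0 + n_cells / A.sum(axis=0))
    return np.log1p(B) * idf


@dataclass
class LSAEmbedding:
    coords: np.ndarray            # kept-cell x component left singular vectors
    singular_values: np.ndarray
    cell_mask: np.ndarray         # cells retained (nonzero rows)
    bin_mask: np.ndarray          # bins retained after both filters


def lsa_embed(
    binary: BinaryAccessibilityMatrix | np.ndarray,
    min_cells_open: int = 10,
    colsum_zmax: float = 2.0,
    n_dims: int = 15,
    scale_by_singular: bool = False,
) -> LSAEmbedding:
    """Latent semantic analysis with log term frequency on a binary matrix.

    Bins open in more than ``min_cells_open`` cells are kept; of those, bins
    whose z-scored column sum is >= ``colsum_zmax`` (promiscuously open) are
    removed. Rows of the filtered matrix A are normalized by their sums (B),
    then C_ij = log(B_ij + 1) * log(1 + n_cells / colsum_j(A)) is decomposed
    by truncated SVD. Left singular vectors are returned unscaled unless
    ``scale_by_singular``; each vector's largest-magnitude element is made
    positive for reproducibility.
    """
    A = binary.values if isinstance(binary, BinaryAccessibilityMatrix) else np.asarray(binary)
    n_cells = A.shape[0]

    colsum = A.sum(axis=0)
    bin_mask = colsum > min_cells_open
    if bin_mask.any():
        kept = colsum[bin_mask].astype(float)
        sd = kept.std()
        z = (kept - kept.mean()) / sd if sd > 0 else np.zeros_like(kept)
        inner = z < colsum_zmax
        idx = np.flatnonzero(bin_mask)
        bin_mask = np.zeros_like(bin_mask)
        bin_mask[idx[inner]] = True
    if not bin_mask.any():
        raise ValueError("all bins removed by the open-cell and column-sum filters")

    A = A[:, bin_mask].astype(float)
    rowsum = A.sum(axis=1)
    cell_mask = rowsum > 0
    if not cell_mask.all():
        warnings.warn(
            f"dropping {int((~cell_mask).sum())} cells with no open bins after filtering",
            stacklevel=2,
        )
    A = A[cell_mask]
    C = log_tf_idf(A, n_cells)

    n_dims = min(n_dims, min(C.shape) - 1) if min(C.shape) > 1 else 1
    U, s, _ = sparse.linalg.svds(C, k=n_dims)
    order = np.argsort(s)[::-1]
    U, s = U[:, order], s[order]
    # sign convention: largest-magnitude element of each vector positive
    flips = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    flips[flips == 0] = 1.0
    U = U * flips
    coords = U * s if scale_by_singular else U
    return LSAEmbedding(coords=coords, singular_values=s, cell_mask=cell_mask, bin_mask=bin_mask)
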