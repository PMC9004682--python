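"""Matrix and position-level file I/O.

Matrices travel as MatrixMarket (.mtx) with TSV sidecars for cell/feature
metadata; ALLC-style per-cytosine tables (chrom, pos, strand, context, mc,
cov) are read with one-upstream-base context filters (HCH, HCG, GCY, HCY)
and aggregated to genomic bins.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

__all__ = [
    "write_matrix",
    "read_matrix",
    "read_allc",
    "context_matches",
    "aggregate_allc_to_bins",
]

_ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov"]

_IUPAC = {"H": set("ACT"), "Y": set("CT"), "N": set("ACGT"),
          "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}}


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a (possibly dense) matrix as sparse MatrixMarket."""
    scipy_io.mmwrite(str(path), sparse.csr_matrix(np.asarray(matrix)))


def read_matrix(path: str | Path) -> np.ndarray:
    return np.asarray(scipy_io.mmread(str(path)).todense())


def read_allc(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=_ALLC_COLUMNS, comment="#")
    return df


def context_matches(context: str, pattern: str) -> bool:
    """Match a cytosine context string against an IUPAC-style pattern.

    Patterns use one upstream base plus the cytosine and downstream bases,
    e.g. "HCH", "HCG", "GCY". The context string must be at least as long
    as the pattern; extra trailing bases are ignored.
    """
    if len(context) < len(pattern):
        return False
    return all(base in _IUPAC[p] for base, p in zip(context, pattern))


def aggregate_allc_to_bins(
    allc: pd.DataFrame, bin_size: int, pattern: str = "HCH"
) -> pd.DataFrame:
    """Sum mc/cov per genomic bin for positions matching a context pattern.

    Bins are 0-based half-open [i*bin_size, (i+1)*bin_size); ALLC positions
    are 1-based.
    """
    sel = allc[allc["context"].map(lambda c: context_matches(c, pattern))].copy()
    sel["bin"] = (sel["pos"] - 1) // bin_size
    agg = (
        sel.groupby(["chrom", "bin"], sort=True)[["mc", "cov"]]
        .sum()
        .reset_index()
    )
    agg["start"] = agg["bin"] * bin_size
    agg["end"] = agg["start"] + bin_size
    return agg[["chrom", "start", "end", "mc", "cov"]]
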