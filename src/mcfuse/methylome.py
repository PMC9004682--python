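"""Methylome preprocessing: QC filters, beta-binomial normalization, HVF selection.

Methylation of a feature (100 kb bin or gene body) in one cell is summarised
by a pair of counts: methylated basecalls ``mc`` and total basecalls ``cov``.
Raw rates ``mc/cov`` are noisy at low coverage, so each cell's rates are
shrunk toward a per-cell beta prior fitted by the method of moments:

    alpha = m (m(1-m)/v - 1),   beta = (1-m)(m(1-m)/v - 1)

with ``m``/``v`` the sample mean and variance of the cell's raw rates. The
posterior rate (alpha + mc) / (alpha + beta + cov) is then divided by the
prior mean m = alpha/(alpha+beta), so a feature with no coverage maps to
exactly 1 and weakly covered features gravitate toward 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "PairedCountMatrix",
    "CellQCThresholds",
    "BetaBinomialPrior",
    "NormalizedRateMatrix",
    "filter_cells",
    "filter_bins",
    "fit_betabinomial_prior",
    "fit_priors",
    "normalize_rates",
    "normalized_dispersion",
    "select_variable_features",
    "embed_methylome",
    "read_blacklist_bed",
    "SNMCAT_COV_BOUNDS",
    "SNMC_COV_BOUNDS",
]

#: mean-coverage bounds for 100 kb bin filtering
SNMC_COV_BOUNDS = (300.0, 3000.0)
#: joint-assay preset (shallower per-context coverage)
SNMCAT_COV_BOUNDS = (250.0, 2500.0)


@dataclass
class PairedCountMatrix:
    """Cell-by-feature methylated (mc) and total (cov) basecall matrices."""

    mc: np.ndarray
    cov: np.ndarray
    context: str = "HCH"
    feature_intervals: pd.DataFrame | None = None  # columns chrom/start/end, BED-style

    def __post_init__(self) -> None:
        self.mc = np.asarray(self.mc)
        self.cov = np.asarray(self.cov)
        if self.mc.shape != self.cov.shape:
            raise ValueError("mc and cov must have the same shape")
        if np.any(self.mc > self.cov):
            raise ValueError("mc must be <= cov element-wise")
        if self.feature_intervals is not None and len(self.feature_intervals) != self.mc.shape[1]:
            raise ValueError("feature_intervals length must match the feature axis")

    @property
    def n_cells(self) -> int:
        return self.mc.shape[0]

    @property
    def n_features(self) -> int:
        return self.mc.shape[1]

    def subset(self, cells=None, features=None) -> "PairedCountMatrix":
        mc, cov = self.mc, self.cov
        intervals = self.feature_intervals
        if cells is not None:
            mc, cov = mc[cells], cov[cells]
        if features is not None:
            mc, cov = mc[:, features], cov[:, features]
            if intervals is not None:
                intervals = intervals.iloc[np.flatnonzero(np.asarray(features))] \
                    if np.asarray(features).dtype == bool else intervals.iloc[features]
                intervals = intervals.reset_index(drop=True)
        return PairedCountMatrix(mc, cov, self.context, intervals)


@dataclass(frozen=True)
class CellQCThresholds:
    """Cell-level QC cutoffs on mapping metrics."""

    max_mccc_rate: float = 0.03
    min_global_mcg: float = 0.5
    max_global_mch: float = 0.2
    min_total_reads: int = 500_000
    min_mapping_rate: float = 0.5


_QC_COLUMNS = ["mccc_rate", "global_mcg", "global_mch", "total_reads", "mapping_rate"]


def filter_cells(
    metrics: pd.DataFrame, thresholds: CellQCThresholds = CellQCThresholds()
) -> np.ndarray:
    """Boolean mask of cells passing all QC criteria.

    The mCCC rate estimates the bisulfite non-conversion upper bound, so high
    values disqualify a cell regardless of the other metrics.
    """
    missing = [c for c in _QC_COLUMNS if c not in metrics.columns]
    if missing:
        raise KeyError(f"missing QC metric columns: {missing}")
    t = thresholds
    mask = (
        (metrics["mccc_rate"] < t.max_mccc_rate)
        & (metrics["global_mcg"] > t.min_global_mcg)
        & (metrics["global_mch"] < t.max_global_mch)
        & (metrics["total_reads"] > t.min_total_reads)
        & (metrics["mapping_rate"] > t.min_mapping_rate)
    )
    return mask.to_numpy()


def read_blacklist_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                      names=["chrom", "start", "end"])
    if (bed["end"] <= bed["start"]).any():
        raise ValueError("malformed BED: end <= start")
    return bed


def _overlaps_blacklist(intervals: pd.DataFrame, blacklist: pd.DataFrame) -> np.ndarray:
    """True for features overlapping any blacklist interval by >= 1 bp."""
    hit = np.zeros(len(intervals), dtype=bool)
    for chrom, black in blacklist.groupby("chrom"):
        sel = np.flatnonzero(intervals["chrom"].to_numpy() == chrom)
        if sel.size == 0:
            continue
        starts = intervals["start"].to_numpy()[sel]
        ends = intervals["end"].to_numpy()[sel]
        for bs, be in zip(black["start"].to_numpy(), black["end"].to_numpy()):
            hit[sel] |= (starts < be) & (ends > bs)
    return hit


def filter_bins(
    counts: PairedCountMatrix,
    min_mean_cov: float = SNMC_COV_BOUNDS[0],
    max_mean_cov: float = SNMC_COV_BOUNDS[1],
    blacklist: pd.DataFrame | None = None,
) -> np.ndarray:
    """Boolean mask of features with usable mean coverage and no blacklist overlap."""
    mean_cov = counts.cov.mean(axis=0)
    keep = (mean_cov >= min_mean_cov) & (mean_cov <= max_mean_cov)
    if blacklist is not None:
        if counts.feature_intervals is None:
            raise ValueError("blacklist filtering requires feature_intervals")
        keep &= ~_overlaps_blacklist(counts.feature_intervals, blacklist)
    return keep


@dataclass(frozen=True)
class BetaBinomialPrior:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(f"prior parameters must be positive, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


class DegeneratePriorError(ValueError):
    """Method of moments invalid: rate variance >= m(1-m) or zero."""


def fit_betabinomial_prior(raw_rates: np.ndarray) -> BetaBinomialPrior:
    """Fit a per-cell beta prior to raw rates by the method of moments.

    ``raw_rates`` should contain only covered features (cov > 0); zero-coverage
    features carry no rate information.
    """
    rates = np.asarray(raw_rates, dtype=float)
    rates = rates[~np.isnan(rates)]
    if rates.size < 2:
        raise ValueError("need >= 2 covered features to fit a prior")
    m = rates.mean()
    v = rates.var()
    if v <= 1e-12:
        raise DegeneratePriorError("raw rates are constant (v = 0)")
    if v >= m * (1 - m):
        raise DegeneratePriorError(
            f"rate variance {v:.4g} >= m(1-m) = {m * (1 - m):.4g}; beta prior undefined"
        )
    scale = m * (1 - m) / v - 1.0
    return BetaBinomialPrior(alpha=m * scale, beta=(1.0 - m) * scale)


def fit_priors(counts: PairedCountMatrix) -> list[BetaBinomialPrior]:
    """Fit one prior per cell from that cell's covered features."""
    priors = []
    for i in range(counts.n_cells):
        covered = counts.cov[i] > 0
        rates = counts.mc[i, covered] / counts.cov[i, covered]
        priors.append(fit_betabinomial_prior(rates))
    return priors


@dataclass
class NormalizedRateMatrix:
    """Posterior methylation rate divided by the cell's prior mean.

    Values are dense and NA-free; zero-coverage entries are exactly 1.
    """

    values: np.ndarray
    context: str = "HCH"


def normalize_rates(
    counts: PairedCountMatrix, priors: list[BetaBinomialPrior]
) -> NormalizedRateMatrix:
    if len(priors) != counts.n_cells:
        raise ValueError("one prior per cell is required")
    alpha = np.array([p.alpha for p in priors])[:, None]
    beta = np.array([p.beta for p in priors])[:, None]
    post = (alpha + counts.mc) / (alpha + beta + counts.cov)
    values = post / (alpha / (alpha + beta))
    return NormalizedRateMatrix(values=values, context=counts.context)


def normalized_dispersion(
    rates: NormalizedRateMatrix | np.ndarray,
    cov: np.ndarray,
    n_mean_bins: int = 20,
    n_cov_bins: int = 5,
) -> np.ndarray:
    """Per-feature dispersion, robustly standardized within mean x coverage bins.

    Both the mean methylation level and the mean coverage of a feature affect
    its rate dispersion, so features are grouped on a 2-D quantile grid of
    (mean rate, mean coverage) and the dispersion (variance/mean) is centred
    and scaled by the median/MAD within each populated grid cell; singleton
    cells get score 0.
    """
    values = rates.values if isinstance(rates, NormalizedRateMatrix) else np.asarray(rates)
    n_features = values.shape[1]
    mean_rate = values.mean(axis=0)
    mean_cov = np.asarray(cov).mean(axis=0)
    disp = values.var(axis=0) / np.maximum(mean_rate, 1e-12)

    def _bin(x: np.ndarray, n_bins: int) -> np.ndarray:
        # quantile bins keep group occupancy even, so no feature is stranded
        # in a sparsely populated outer bin
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
        if edges.size < 2:
            return np.zeros(x.size, dtype=int)
        return np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)

    group = _bin(mean_rate, n_mean_bins) * n_cov_bins + _bin(mean_cov, n_cov_bins)
    zscores = np.zeros(n_features)
    for g in np.unique(group):
        members = np.flatnonzero(group == g)
        if members.size < 2:
            continue  # singleton group: z stays 0
        d = disp[members]
        # robust centering: a handful of genuinely variable features in a bin
        # must not inflate the bin's own scale
        med = np.median(d)
        mad = 1.4826 * np.median(np.abs(d - med))
        scale = mad if mad > 0 else d.std()
        if scale > 0:
            zscores[members] = (d - med) / scale
    return zscores


def select_variable_features(
    rates: NormalizedRateMatrix | np.ndarray,
    cov: np.ndarray,
    n_top: int = 3000,
    n_mean_bins: int = 20,
    n_cov_bins: int = 5,
) -> np.ndarray:
    """Indices of the ``n_top`` features with the highest normalized dispersion.

    See :func:`normalized_dispersion`; ties break by ascending feature index.
    """
    values = rates.values if isinstance(rates, NormalizedRateMatrix) else np.asarray(rates)
    n_features = values.shape[1]
    if n_top > n_features:
        raise ValueError(f"n_top={n_top} exceeds the number of features {n_features}")
    zscores = normalized_dispersion(values, cov, n_mean_bins, n_cov_bins)
    order = np.lexsort((np.arange(n_features), -zscores))
    return order[:n_top]


def embed_methylome(
    rates: NormalizedRateMatrix | np.ndarray,
    selected: np.ndarray | None = None,
    n_components: int = 20,
    random_state: int = 0,
) -> np.ndarray:
    """Z-score selected features per feature and project onto principal components.

    The number of components is an explicit choice (default 20); inspect the
    PCA variance ratio to adjust it for a given dataset.
    """
    values = rates.values if isinstance(rates, NormalizedRateMatrix) else np.asarray(rates)
    if selected is not None:
        values = values[:, selected]
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    scaled = (values - values.mean(axis=0)) / sd
    n_components = min(n_components, *scaled.shape)
    return PCA(n_components=n_components, random_state=random_state).fit_transform(scaled)
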