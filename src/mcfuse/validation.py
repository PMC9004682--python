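"""Cross-modal cluster validation.

When the same cells are profiled in two modalities (e.g. gene-body mCH and
RNA), the second modality provides an independent check on clusters defined
in the first. The tools here treat the two modalities as if they came from
separate experiments, co-embed them with canonical correlation analysis
(SVD of X Y^T after column standardization), and derive:

- *k-partners*: a cell's k nearest cross-modal neighbors in the co-embedding;
- an over-splitting score S_over per cluster — the fraction of within-cluster
  cells' k-partners (k = cluster size) that fall outside the cluster; 0 means
  no over-splitting;
- a self-radius per cell — the number of cross-modal profiles closer to the
  cell's X-profile than its own Y-profile — whose within-cluster distribution
  is uniform for a homogeneous cluster; the under-splitting score S_under is
  the slope of its cumulative distribution at the lower quartile (1 for an
  ideal cluster, > 1 when the cluster hides substructure);
- cross-validated cluster-number selection: cluster on one modality, score
  cell-vs-centroid MSE on the other, with AIC/BIC analogues
  AIC = MSE + 2 d sigma^2 / N and BIC = MSE + ln(N) d sigma^2 / N;
- data-fusion quality metrics (rank self-radius d/2N, mis-fusion ratio,
  co-cluster accuracy) and cluster overlap scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._graph import knn_graph, leiden, leiden_at_cluster_count

__all__ = [
    "CoEmbedding",
    "ValidationCurve",
    "SplitScores",
    "FusionMetrics",
    "cca_coembed",
    "cross_modal_partners",
    "over_splitting_score",
    "self_radii",
    "under_splitting_score",
    "split_scores",
    "make_ideal_reference",
    "cv_error_curve",
    "information_criteria",
    "evaluate_fusion",
    "overlap_score",
]


@dataclass
class CoEmbedding:
    """Paired low-dimensional coordinates (same cells, two modalities)."""

    U: np.ndarray  # modality X, cells x components
    V: np.ndarray  # modality Y, cells x components
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_components(self) -> int:
        return self.U.shape[1]


def _standardize_columns(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score columns; drop columns that are constant in either matrix."""
    keep = (X.std(axis=0) > 0) & (Y.std(axis=0) > 0)
    X, Y = X[:, keep], Y[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    Y = (Y - Y.mean(axis=0)) / Y.std(axis=0)
    return X, Y


def cca_coembed(
    X: np.ndarray, Y: np.ndarray, n_components: int = 20, scale_by_singular: bool = True
) -> CoEmbedding:
    """Co-embed two cell-by-gene matrices by SVD of X Y^T.

    Columns (shared genes) are standardized in each modality; zero-variance
    columns are dropped from both. The left/right singular vectors place the
    X-cells and Y-cells in a common space. Components beyond the numerical
    rank are dropped with a warning.

    By default coordinates are scaled by the singular values so that
    components carrying more cross-modal covariance dominate distances;
    pass ``scale_by_singular=False`` for orthonormal coordinates.

    Note that a modality anti-correlated with the other (e.g. gene-body mCH
    against expression) must be sign-reversed (``X.max() - X``) beforehand,
    otherwise the two sides of the embedding anti-align.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of cells")
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share aligned gene columns")
    Xs, Ys = _standardize_columns(X, Y)
    if Xs.shape[1] == 0:
        raise ValueError("no non-constant shared genes")
    K = Xs @ Ys.T
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    tol = s.max() * max(K.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but numerical rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    U, s, V = U[:, :n_components], s[:n_components], Vt[:n_components].T
    flips = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    flips[flips == 0] = 1.0
    U, V = U * flips, V * flips
    if scale_by_singular:
        U, V = U * s, V * s
    return CoEmbedding(U=U, V=V, singular_values=s)


def _cross_distances(embedding: CoEmbedding) -> np.ndarray:
    return cdist(embedding.U, embedding.V)


def cross_modal_partners(embedding: CoEmbedding, k: int) -> np.ndarray:
    """For each X-cell, its k nearest Y-cells (ties broken by ascending index)."""
    D = _cross_distances(embedding)
    if k > D.shape[1]:
        raise ValueError(f"k={k} exceeds the number of cells {D.shape[1]}")
    order = np.argsort(D, axis=1, kind="stable")  # stable: ties by index
    return order[:, :k]


def over_splitting_score(embedding: CoEmbedding, labels: np.ndarray) -> pd.Series:
    """Per-cluster S_over: fraction of cells' k-partners (k = cluster size)
    drawn from other clusters. 0 means no over-splitting; bounded by 1."""
    labels = np.asarray(labels)
    D = _cross_distances(embedding)
    order = np.argsort(D, axis=1, kind="stable")
    n = labels.size
    scores = {}
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        k = min(members.size, n)
        partners = order[members, :k]
        same = (labels[partners] == c).sum()
        scores[c] = 1.0 - same / (members.size * k)
    return pd.Series(scores, name="S_over")


def self_radii(embedding: CoEmbedding) -> np.ndarray:
    """Number of cross-modal profiles strictly closer to each cell's X-profile
    than its own Y-profile (its cross-modal self-distance)."""
    D = _cross_distances(embedding)
    self_d = np.diag(D)
    closer = (D < self_d[:, None]).sum(axis=1)
    # strict inequality already excludes the self column (d_ii < d_ii is false)
    return closer.astype(np.int64)


def under_splitting_score(
    radii: np.ndarray, labels: np.ndarray, quantile: float = 0.25
) -> pd.Series:
    """Per-cluster S_under: slope of the cumulative distribution of the
    normalized self-radius rho = r/|C| evaluated at ``quantile``.

    Homogeneous clusters have uniform rho so the slope is ~1; under-split
    clusters concentrate small radii and score > 1.
    """
    radii = np.asarray(radii)
    labels = np.asarray(labels)
    scores = {}
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise ValueError(f"empty cluster {c!r}")
        rho = radii[members] / members.size
        scores[c] = float((rho <= quantile).mean() / quantile)
    return pd.Series(scores, name="S_under")


@dataclass
class SplitScores:
    s_over: pd.Series
    s_under: pd.Series
    cluster_sizes: pd.Series


def split_scores(embedding: CoEmbedding, labels: np.ndarray, quantile: float = 0.25) -> SplitScores:
    """Convenience bundle of S_over and S_under for one clustering."""
    labels = np.asarray(labels)
    sizes = pd.Series(labels).value_counts().sort_index()
    return SplitScores(
        s_over=over_splitting_score(embedding, labels),
        s_under=under_splitting_score(self_radii(embedding), labels, quantile),
        cluster_sizes=sizes,
    )


def make_ideal_reference(
    features_x: np.ndarray, features_y: np.ndarray, labels: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Destroy within-cluster cell identity while preserving per-gene marginals.

    Within each cluster, each gene column is permuted across cells
    independently, separately in each modality. The result is a homogeneous
    ("ideal") version of every cluster: cluster-level structure survives but
    the cross-modal pairing of individual cells is random.
    """
    rng = np.random.default_rng(seed)
    X = np.array(features_x, dtype=float, copy=True)
    Y = np.array(features_y, dtype=float, copy=True)
    labels = np.asarray(labels)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        for M in (X, Y):
            block = M[members]
            for j in range(block.shape[1]):
                M[members, j] = block[rng.permutation(members.size), j]
    return X, Y


@dataclass
class ValidationCurve:
    """Per-granularity train/test error with information criteria."""

    table: pd.DataFrame  # columns: resolution, n_clusters, train_mse, test_mse, aic, bic, ...

    def optimum(self, column: str = "test_mse") -> int:
        """n_clusters minimizing the mean of ``column`` across replicates."""
        mean = self.table.groupby("n_clusters")[column].mean()
        return int(mean.idxmin())


def information_criteria(
    train_mse: float, N: int, d: int, sigma2: float
) -> tuple[float, float]:
    """AIC/BIC analogues for centroid models: penalty per extra cluster.

    Under a Gaussian cell-around-centroid model with d clusters and N cells,
    AIC = MSE + 2 d sigma^2 / N and BIC = MSE + ln(N) d sigma^2 / N.
    """
    if N <= 0 or d < 1:
        raise ValueError("N must be positive and d >= 1")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    aic = train_mse + 2.0 * d * sigma2 / N
    bic = train_mse + np.log(N) * d * sigma2 / N
    return float(aic), float(bic)


def cv_error_curve(
    cluster_modality: np.ndarray,
    eval_modality: np.ndarray,
    resolutions: list[float],
    n_folds: int = 5,
    n_seeds: int = 5,
    n_pcs: int = 20,
    k_neighbors: int = 25,
    sigma2: float | None = None,
    seed: int = 0,
) -> ValidationCurve:
    """Cluster on one modality, score centroid fit on the other.

    For each resolution, Leiden clustering runs on the top principal
    components of ``cluster_modality`` (one seeded run per replicate seed);
    cells are split into random folds; centroids of ``eval_modality`` are
    estimated from the training folds and the mean squared error of cells
    against their cluster centroid is recorded for train and test cells.
    sigma^2 for AIC/BIC defaults to the mean per-feature variance of the
    evaluation modality (single-cluster assumption).
    """
    from sklearn.decomposition import PCA
    from sklearn.model_selection import KFold

    X = np.asarray(cluster_modality, float)
    E = np.asarray(eval_modality, float)
    if X.shape[0] != E.shape[0]:
        raise ValueError("both modalities must contain the same cells")
    n = X.shape[0]
    if sigma2 is None:
        sigma2 = float(E.var(axis=0).mean())

    n_pcs = min(n_pcs, n - 1, X.shape[1])
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(
        (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
    )
    graph = knn_graph(pcs, k_neighbors)

    rows = []
    for res in resolutions:
        for rep in range(n_seeds):
            labels = leiden(graph, resolution=res, seed=seed + rep)
            d = int(labels.max()) + 1
            kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
            for fold, (train, test) in enumerate(kf.split(np.arange(n))):
                centroids = np.empty((d, E.shape[1]))
                global_mean = E[train].mean(axis=0)
                for c in range(d):
                    tr = train[labels[train] == c]
                    centroids[c] = E[tr].mean(axis=0) if tr.size else global_mean
                train_mse = float(((E[train] - centroids[labels[train]]) ** 2).mean())
                test_mse = float(((E[test] - centroids[labels[test]]) ** 2).mean())
                aic, bic = information_criteria(train_mse, n, d, sigma2)
                rows.append(
                    dict(resolution=res, replicate=rep, fold=fold, n_clusters=d,
                         train_mse=train_mse, test_mse=test_mse, aic=aic, bic=bic)
                )
    return ValidationCurve(table=pd.DataFrame(rows))


@dataclass
class FusionMetrics:
    normalized_self_radius: np.ndarray  # per cell, rank / 2N
    misfusion_ratio: float
    cocluster_accuracy: float
    cocluster_labels: np.ndarray
    n_coclusters: int


def evaluate_fusion(
    joint_coords: np.ndarray,
    cell_pairs: np.ndarray,
    misfusion_threshold: float = 0.3,
    target_n_coclusters: int | None = None,
    k_neighbors: int = 30,
    seed: int = 0,
) -> FusionMetrics:
    """Score a fused embedding that contains both profiles of every cell.

    ``cell_pairs`` is an (N, 2) array of row indices into ``joint_coords``
    giving each cell's X-profile and Y-profile rows. For each cell the rank
    d of its Y-row in the distance-ordered neighbor list of its X-row
    (1-based, self excluded) is normalized by the number of rows (2N);
    cells with normalized rank above ``misfusion_threshold`` count as
    mis-fused. Co-clusters come from Leiden with the resolution bisected to
    reach ``target_n_coclusters``; accuracy is the fraction of cells whose
    two profiles co-cluster.
    """
    coords = np.asarray(joint_coords, float)
    pairs = np.asarray(cell_pairs)
    total = coords.shape[0]
    if pairs.max() >= total:
        raise ValueError("cell_pairs index outside joint_coords")

    D = cdist(coords[pairs[:, 0]], coords)
    ranks = np.empty(pairs.shape[0], dtype=np.int64)
    for i, (xrow, yrow) in enumerate(pairs):
        d_self = D[i, yrow]
        # rank among all rows except the query's own row; ties resolved by index
        closer = np.sum(D[i] < d_self) + np.sum((D[i] == d_self) & (np.arange(total) < yrow))
        closer -= int(D[i, xrow] < d_self or (D[i, xrow] == d_self and xrow < yrow))
        ranks[i] = closer + 1
    normalized = ranks / total
    misfusion = float((normalized > misfusion_threshold).mean())

    graph = knn_graph(coords, min(k_neighbors, total - 1))
    if target_n_coclusters is None:
        labels = leiden(graph, resolution=1.0, seed=seed)
    else:
        labels = leiden_at_cluster_count(graph, target_n_coclusters, seed=seed)
    accuracy = float((labels[pairs[:, 0]] == labels[pairs[:, 1]]).mean())
    return FusionMetrics(
        normalized_self_radius=normalized,
        misfusion_ratio=misfusion,
        cocluster_accuracy=accuracy,
        cocluster_labels=labels,
        n_coclusters=int(np.unique(labels).size),
    )


def overlap_score(
    labels_a: np.ndarray, labels_b: np.ndarray, coclusters: np.ndarray
) -> pd.DataFrame:
    """Cluster correspondence via a joint co-clustering.

    score(a, b) = sum over co-clusters g of min(|a ∩ g|/|a|, |b ∩ g|/|b|).
    ``coclusters`` either aligns with both label vectors (shared cells) or is
    the concatenation of the A-cell and B-cell co-cluster assignments
    (disjoint cell sets). Scores lie in [0, 1]; 1 means the two clusters
    always co-cluster together.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    cc = np.asarray(coclusters)
    if cc.size == a.size + b.size:
        cc_a, cc_b = cc[: a.size], cc[a.size :]
    elif cc.size == a.size and cc.size == b.size:
        cc_a = cc_b = cc
    else:
        raise ValueError("coclusters must align with the cells of both labelings")

    ua, ub = np.unique(a), np.unique(b)
    ug = np.unique(np.concatenate([cc_a, cc_b]))
    prop_a = np.zeros((ua.size, ug.size))
    prop_b = np.zeros((ub.size, ug.size))
    for i, ca in enumerate(ua):
        members = cc_a[a == ca]
        if members.size == 0:
            raise ValueError(f"empty cluster {ca!r} in labels_a")
        for j, g in enumerate(ug):
            prop_a[i, j] = (members == g).mean()
    for i, cb in enumerate(ub):
        members = cc_b[b == cb]
        if members.size == 0:
            raise ValueError(f"empty cluster {cb!r} in labels_b")
        for j, g in enumerate(ug):
            prop_b[i, j] = (members == g).mean()
    scores = np.minimum(prop_a[:, None, :], prop_b[None, :, :]).sum(axis=2)
    return pd.DataFrame(scores, index=ua, columns=ub)
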