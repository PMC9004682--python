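"""Leiden ensemble consensus clustering with supervised evaluation.

Leiden clustering is stochastic: different random starts on the same KNN
graph produce slightly different partitions. To absorb that randomness the
clustering is repeated many times (default 200) and the runs are combined by
density-based consensus: the distance between two cells is the fraction of
runs assigning them different labels (a label-permutation-safe Hamming
distance), and outlier-aware DBSCAN over that distance yields consensus
versions spanning the range of cluster counts seen across runs.

Each consensus version is scored by a supervised reproducibility check: a
class-imbalance-aware multiclass classifier with recursive feature
elimination under cross-validation is trained on 90% of the non-outlier
cells and scored by balanced accuracy on the held-out 10%. The trained model
also rescues outliers whose predicted class probability exceeds 0.5. The
final resolution is the largest one whose version keeps outliers below 5%,
model performance above 0.95, and mean cluster size at least 30 cells.

Markers are called one-vs-rest (rank-sum test, Benjamini-Hochberg); clusters
with too few markers are merged into their nearest centroid neighbor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN

from ._graph import knn_graph, leiden

__all__ = [
    "OUTLIER",
    "ClusteringEnsemble",
    "ConsensusVersion",
    "run_leiden_ensemble",
    "consensus_partition",
    "evaluate_partition",
    "rescue_outliers",
    "select_resolution",
    "find_markers",
    "markers_per_cluster",
    "merge_weak_clusters",
]

#: sentinel label for cells not assigned to any consensus cluster
OUTLIER = -1


@dataclass
class ClusteringEnsemble:
    assignments: np.ndarray  # cells x runs
    resolution: float
    seeds: list[int]

    @property
    def n_runs(self) -> int:
        return self.assignments.shape[1]

    def cluster_count_range(self) -> tuple[int, int]:
        counts = [np.unique(self.assignments[:, r]).size for r in range(self.n_runs)]
        return min(counts), max(counts)


@dataclass
class ConsensusVersion:
    labels: np.ndarray  # per-cell int label, OUTLIER for unassigned
    epsilon: float
    resolution: float = np.nan

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels[self.labels != OUTLIER]).size)

    @property
    def outlier_fraction(self) -> float:
        return float((self.labels == OUTLIER).mean())

    @property
    def mean_cluster_size(self) -> float:
        n = self.n_clusters
        return float((self.labels != OUTLIER).sum() / n) if n else 0.0


def run_leiden_ensemble(
    embedding: np.ndarray,
    k_neighbors: int = 25,
    resolution: float = 1.0,
    n_runs: int = 200,
    seed: int = 0,
) -> ClusteringEnsemble:
    """Repeat Leiden with different random starts on one shared KNN graph."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    graph = knn_graph(embedding, k_neighbors)
    seeds = [seed + r for r in range(n_runs)]
    runs = np.column_stack([leiden(graph, resolution=resolution, seed=s) for s in seeds])
    return ClusteringEnsemble(assignments=runs, resolution=resolution, seeds=seeds)


def consensus_distance(ensemble: ClusteringEnsemble) -> np.ndarray:
    """Pairwise fraction of runs in which two cells get different labels."""
    A = ensemble.assignments
    n = A.shape[0]
    disagree = np.zeros((n, n))
    for r in range(A.shape[1]):
        col = A[:, r]
        disagree += col[:, None] != col[None, :]
    return disagree / A.shape[1]


def consensus_partition(
    ensemble: ClusteringEnsemble,
    epsilon_grid: np.ndarray | None = None,
    min_samples: int = 5,
) -> list[ConsensusVersion]:
    """Density-consensus versions across a grid of DBSCAN radii.

    Returns one version per distinct cluster count (keeping, per count, the
    version with fewest outliers), sorted by increasing cluster count.
    """
    if epsilon_grid is None:
        epsilon_grid = np.linspace(0.02, 1.0, 50)
    epsilon_grid = np.asarray(epsilon_grid, float)
    if epsilon_grid.size == 0:
        raise ValueError("epsilon grid must be non-empty")
    D = consensus_distance(ensemble)
    by_count: dict[int, ConsensusVersion] = {}
    for eps in epsilon_grid:
        labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit_predict(D)
        version = ConsensusVersion(
            labels=labels.astype(np.int64), epsilon=float(eps), resolution=ensemble.resolution
        )
        k = version.n_clusters
        if k == 0:
            continue
        best = by_count.get(k)
        if best is None or version.outlier_fraction < best.outlier_fraction:
            by_count[k] = version
    return [by_count[k] for k in sorted(by_count)]


def evaluate_partition(
    embedding: np.ndarray,
    labels: np.ndarray,
    holdout_fraction: float = 0.1,
    n_folds: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
):
    """Supervised reproducibility score for a consensus version.

    Outliers are excluded; 10% of cells are held out; the remaining cells
    train a balanced random forest under recursive feature (component)
    elimination with cross-validation, scored by balanced accuracy. Returns
    the held-out balanced accuracy and the fitted selector/model (which
    exposes ``predict_proba`` for outlier rescue).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.feature_selection import RFECV
    from sklearn.metrics import balanced_accuracy_score
    from sklearn.model_selection import StratifiedKFold, train_test_split

    labels = np.asarray(labels)
    mask = labels != OUTLIER
    X, y = np.asarray(embedding)[mask], labels[mask]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("supervised evaluation requires >= 2 clusters")

    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=holdout_fraction, stratify=y, random_state=seed
    )
    smallest = np.unique(y_train, return_counts=True)[1].min()
    if smallest < n_folds:
        warnings.warn(
            f"smallest cluster has {smallest} training cells; reducing folds from {n_folds}",
            stacklevel=2,
        )
        n_folds = max(2, int(smallest))
    clf = RandomForestClassifier(
        n_estimators=n_estimators, class_weight="balanced_subsample", random_state=seed
    )
    model = RFECV(
        clf,
        step=1,
        cv=StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed),
        scoring="balanced_accuracy",
        min_features_to_select=2,
    )
    model.fit(X_train, y_train)
    score = balanced_accuracy_score(y_test, model.predict(X_test))
    return float(score), model


def rescue_outliers(
    model,
    embedding: np.ndarray,
    labels: np.ndarray,
    prob_threshold: float = 0.5,
) -> np.ndarray:
    """Assign outliers their predicted class when its probability exceeds the cutoff."""
    labels = np.asarray(labels).copy()
    outliers = np.flatnonzero(labels == OUTLIER)
    if outliers.size == 0:
        return labels
    proba = model.predict_proba(np.asarray(embedding)[outliers])
    classes = model.classes_
    best = proba.argmax(axis=1)
    confident = proba[np.arange(outliers.size), best] > prob_threshold
    labels[outliers[confident]] = classes[best[confident]]
    return labels


class ResolutionSelectionError(RuntimeError):
    pass


def select_resolution(
    candidates: list[tuple[float, ConsensusVersion, float]],
    max_outlier_fraction: float = 0.05,
    min_score: float = 0.95,
    min_mean_cluster_size: float = 30.0,
) -> float:
    """Largest resolution whose version meets all three stability criteria.

    A higher resolution splits more finely; the criteria (few outliers, high
    supervised reproducibility, adequate cluster size) all guard against
    over-splitting, so the maximum qualifying resolution is chosen.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    qualifying = []
    violations = []
    for res, version, score in candidates:
        problems = []
        if not version.outlier_fraction < max_outlier_fraction:
            problems.append(f"outlier_fraction={version.outlier_fraction:.3f}")
        if not score > min_score:
            problems.append(f"score={score:.3f}")
        if not version.mean_cluster_size >= min_mean_cluster_size:
            problems.append(f"mean_cluster_size={version.mean_cluster_size:.1f}")
        if problems:
            violations.append(f"resolution {res}: " + ", ".join(problems))
        else:
            qualifying.append(res)
    if not qualifying:
        raise ResolutionSelectionError(
            "no resolution satisfies all criteria:\n" + "\n".join(violations)
        )
    return max(qualifying)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(pvals, method="bh")


def find_markers(
    matrix: np.ndarray,
    labels: np.ndarray,
    modality: str = "rna",
    max_adj_p: float = 0.01,
    min_log2fc: float = 1.0,
    max_delta: float = -0.3,
    min_auroc: float = 0.8,
    genes: np.ndarray | None = None,
) -> pd.DataFrame:
    """One-vs-rest marker statistics per (cluster, gene).

    RNA markers are up-regulated: rank-sum test (greater), BH-adjusted
    p < 0.01, log2 fold-change > 1, AUROC > 0.8. Methylation markers are
    hypo-methylated: the same test with reversed direction, delta (cluster
    mean minus the mean of the other clusters' means) < -0.3, AUROC (for the
    "lower" direction) > 0.8. Returns the full table with a ``significant``
    flag; singleton clusters are skipped with a warning.
    """
    if modality not in {"rna", "mch", "mcg"}:
        raise ValueError(f"unknown modality {modality!r}")
    X = np.asarray(matrix, float)
    labels = np.asarray(labels)
    gene_names = np.asarray(genes) if genes is not None else np.arange(X.shape[1])
    clusters = [c for c in np.unique(labels) if c != OUTLIER]
    if len(clusters) < 2:
        raise ValueError("marker detection requires >= 2 clusters")
    hypo = modality in {"mch", "mcg"}

    cluster_means = {c: X[labels == c].mean(axis=0) for c in clusters}
    rows = []
    for c in clusters:
        in_mask = labels == c
        rest_mask = (~in_mask) & (labels != OUTLIER)
        n1, n2 = int(in_mask.sum()), int(rest_mask.sum())
        if n1 < 2:
            warnings.warn(f"cluster {c!r} has fewer than 2 cells; skipped", stacklevel=2)
            continue
        alt = "less" if hypo else "greater"
        u, p = stats.mannwhitneyu(X[in_mask], X[rest_mask], alternative=alt, axis=0)
        auroc = u / (n1 * n2)
        if hypo:
            auroc = 1.0 - auroc  # P(in-cluster value below the rest)
        padj = _bh_adjust(p)
        if hypo:
            others = np.mean([cluster_means[o] for o in clusters if o != c], axis=0)
            effect = cluster_means[c] - others
            passing = (padj < max_adj_p) & (effect < max_delta) & (auroc > min_auroc)
        else:
            mean_in = X[in_mask].mean(axis=0)
            mean_rest = X[rest_mask].mean(axis=0)
            effect = np.log2((mean_in + 1e-9) / (mean_rest + 1e-9))
            passing = (padj < max_adj_p) & (effect > min_log2fc) & (auroc > min_auroc)
        rows.append(
            pd.DataFrame(
                dict(cluster=c, gene=gene_names, pval=p, adj_pval=padj,
                     effect=effect, auroc=auroc, significant=passing)
            )
        )
    return pd.concat(rows, ignore_index=True)


def markers_per_cluster(markers: pd.DataFrame) -> pd.Series:
    """Count of significant markers per cluster (0 for clusters with none)."""
    sig = markers[markers["significant"]]
    counts = sig.groupby("cluster").size()
    return counts.reindex(markers["cluster"].unique(), fill_value=0)


def merge_weak_clusters(
    matrix: np.ndarray,
    labels: np.ndarray,
    embedding: np.ndarray,
    modality: str = "rna",
    min_markers: int = 10,
    **marker_kwargs,
) -> np.ndarray:
    """Merge clusters lacking markers into their nearest centroid neighbor.

    While any cluster has fewer than ``min_markers`` significant markers, the
    weakest cluster is merged into the cluster with the nearest centroid in
    the clustering embedding (ties to the larger cluster), and markers are
    recomputed. Terminates when every cluster has enough markers or only one
    cluster remains.
    """
    labels = np.asarray(labels).copy()
    emb = np.asarray(embedding, float)
    while True:
        clusters = [c for c in np.unique(labels) if c != OUTLIER]
        if len(clusters) < 2:
            return labels
        counts = markers_per_cluster(
            find_markers(matrix, labels, modality=modality, **marker_kwargs)
        ).reindex(clusters, fill_value=0)
        if (counts >= min_markers).all():
            return labels
        weakest = counts.idxmin()
        centroids = {c: emb[labels == c].mean(axis=0) for c in clusters}
        sizes = {c: int((labels == c).sum()) for c in clusters}
        others = [c for c in clusters if c != weakest]
        dists = np.array([np.linalg.norm(centroids[weakest] - centroids[o]) for o in others])
        best = dists.min()
        tied = [o for o, d in zip(others, dists) if d == best]
        target = max(tied, key=lambda c: sizes[c])  # tie-break: larger cluster
        labels[labels == weakest] = target
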