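"""Cross-modality data fusion.

Cells measured in different modalities (methylome, transcriptome, ATAC) are
integrated by (1) diffusion smoothing within each modality, (2) co-embedding
by CCA, (3) capacity-constrained cross-modal matching ("restricted
k-partners"), (4) imputation of the missing modality by averaging partners'
smoothed features, and (5) joint PCA + Leiden clustering of measured and
imputed profiles.

The restricted k-partner (RKP) step avoids hub cells: iterating over source
cells in random order k times, each source connects to its most similar
eligible target, and any target reaching k' = ceil(z k N_source / N_target)
partners leaves the eligible pool. With z = 1 every target ends with k' or
k' - 1 partners; z = 3 (default) lets a target collect at most three times
the average load.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._graph import knn_graph, leiden
from .validation import cca_coembed

__all__ = [
    "SmoothingOperator",
    "PartnerGraph",
    "FusionResult",
    "build_smoothing_operator",
    "smooth_features",
    "restricted_k_partners",
    "impute_cross_modality",
    "fuse_datasets",
    "transfer_labels",
]

UNASSIGNED = "UNASSIGNED"

#: default self-weight of the smoothing operator per modality
DEFAULT_P = {"mch": 0.9, "mcg": 0.9, "rna": 0.7}


@dataclass
class SmoothingOperator:
    """Row-stochastic diffusion weights W = p I + (1 - p) A_rownorm."""

    weights: sparse.csr_matrix
    k: int
    ka: int
    p: float


def build_smoothing_operator(
    coords: np.ndarray, k: int = 30, ka: int = 5, p: float = 0.9
) -> SmoothingOperator:
    """Gaussian-kernel diffusion operator on the kNN graph.

    The kernel bandwidth sigma_i is each cell's distance to its ka-th
    neighbor (adaptive); the kernel matrix is zeroed outside the kNN and on
    the diagonal, symmetrized by addition, row-normalized, and mixed with
    the identity: W = p I + (1 - p) A. Duplicate points (sigma = 0) fall
    back to the smallest positive neighbor distance with a warning.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if not 0 <= ka < k < n:
        raise ValueError(f"need 0 <= ka < k < n_cells, got ka={ka}, k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    sigma = dist[:, ka - 1].copy() if ka >= 1 else dist[:, 0].copy()
    zero = sigma == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cells have duplicate neighbors (sigma = 0); "
            "using the smallest positive neighbor distance",
            stacklevel=2,
        )
        for i in np.flatnonzero(zero):
            positive = dist[i][dist[i] > 0]
            sigma[i] = positive.min() if positive.size else 1.0

    kernel = np.exp(-(dist**2) / sigma[:, None] ** 2)
    rows = np.repeat(np.arange(n), k)
    A1 = sparse.coo_matrix((kernel.ravel(), (rows, idx.ravel())), shape=(n, n)).tocsr()
    A1.setdiag(0.0)
    A2 = A1 + A1.T
    rowsum = np.asarray(A2.sum(axis=1)).ravel()
    rowsum[rowsum == 0] = 1.0
    A3 = sparse.diags(1.0 / rowsum) @ A2
    W = p * sparse.eye(n, format="csr") + (1.0 - p) * A3.tocsr()
    return SmoothingOperator(weights=W.tocsr(), k=k, ka=ka, p=p)


def smooth_features(features: np.ndarray, op: SmoothingOperator) -> np.ndarray:
    features = np.asarray(features, float)
    if features.shape[0] != op.weights.shape[0]:
        raise ValueError("feature matrix and operator disagree on cell count")
    return np.asarray(op.weights @ features)


@dataclass
class PartnerGraph:
    """Directed cross-modal partner lists with target capacity bookkeeping."""

    partners: np.ndarray  # n_source x k target indices
    k_prime: int
    z: float
    target_counts: np.ndarray

    @property
    def k(self) -> int:
        return self.partners.shape[1]


def _pairwise_distance(source: np.ndarray, target: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return cdist(source, target)
    if metric == "one_minus_spearman":
        rs = stats.rankdata(source, axis=1)
        rt = stats.rankdata(target, axis=1)
        rs = (rs - rs.mean(axis=1, keepdims=True)) / rs.std(axis=1, keepdims=True)
        rt = (rt - rt.mean(axis=1, keepdims=True)) / rt.std(axis=1, keepdims=True)
        return 1.0 - rs @ rt.T / source.shape[1]
    raise ValueError(f"unknown metric {metric!r}")


def restricted_k_partners(
    source_coords: np.ndarray,
    target_coords: np.ndarray,
    k: int,
    z: float = 3.0,
    seed: int = 0,
    metric: str = "euclidean",
) -> PartnerGraph:
    """Match every source cell to k distinct targets under a capacity cap.

    Runs k rounds; each round iterates the source cells in a fresh seeded
    random order and connects each to its nearest eligible target it has not
    already partnered. Targets at capacity k' = ceil(z k N_s / N_t) become
    ineligible. Distance ties break toward the lower target index.
    """
    if z < 1:
        raise ValueError(f"relaxation z must be >= 1, got {z}")
    source = np.asarray(source_coords, float)
    target = np.asarray(target_coords, float)
    n_s, n_t = source.shape[0], target.shape[0]
    if k > n_t:
        raise ValueError(f"k={k} exceeds the number of target cells {n_t}")
    k_prime = math.ceil(z * k * n_s / n_t)
    rng = np.random.default_rng(seed)

    D = _pairwise_distance(source, target, metric)
    order = np.argsort(D, axis=1, kind="stable")  # ties by ascending index
    pointer = np.zeros(n_s, dtype=np.int64)  # lazily advanced per source
    counts = np.zeros(n_t, dtype=np.int64)
    eligible = np.ones(n_t, dtype=bool)
    chosen = [set() for _ in range(n_s)]
    partners = np.full((n_s, k), -1, dtype=np.int64)

    for round_i in range(k):
        for i in rng.permutation(n_s):
            row = order[i]
            ptr = pointer[i]
            while ptr < n_t and (not eligible[row[ptr]] or row[ptr] in chosen[i]):
                ptr += 1
            if ptr >= n_t:
                # all remaining targets are this source's partners already;
                # relax distinctness for this pick
                fallback = row[eligible[row]]
                if fallback.size == 0:
                    raise RuntimeError("no eligible target cells remain")
                j = int(fallback[0])
                warnings.warn("duplicate partner assigned after target exhaustion", stacklevel=2)
            else:
                j = int(row[ptr])
                pointer[i] = ptr  # chosen targets stay ineligible or chosen; safe to keep
            partners[i, round_i] = j
            chosen[i].add(j)
            counts[j] += 1
            if counts[j] >= k_prime:
                eligible[j] = False
    return PartnerGraph(partners=partners, k_prime=k_prime, z=z, target_counts=counts)


def impute_cross_modality(graph: PartnerGraph, target_features: np.ndarray) -> np.ndarray:
    """Average the smoothed target-modality features of each source cell's partners."""
    features = np.asarray(target_features, float)
    if graph.partners.max() >= features.shape[0]:
        raise IndexError("partner id outside target feature matrix")
    return features[graph.partners].mean(axis=1)


@dataclass
class FusionResult:
    joint_pcs: np.ndarray          # (n_a + n_b) x n_pcs, rows: A cells then B cells
    labels_a: np.ndarray
    labels_b: np.ndarray
    graph: PartnerGraph
    coembedding: object
    source_modality: str           # which side was imputed
    umap_coords: np.ndarray | None = None

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate([self.labels_a, self.labels_b])


def fuse_datasets(
    meth_features: np.ndarray,
    rna_features: np.ndarray,
    n_cca: int = 50,
    k: int = 30,
    z: float = 3.0,
    p_meth: float = 0.9,
    p_rna: float = 0.7,
    n_pcs: int = 50,
    k_graph: int = 30,
    resolution: float = 1.0,
    metric: str = "euclidean",
    reverse_meth: bool = True,
    impute_direction: str = "auto",
    compute_umap: bool = False,
    seed: int = 0,
) -> FusionResult:
    """Fuse a methylome and a transcriptome dataset over shared genes.

    Both inputs are cell-by-gene matrices restricted to the same gene set
    (typically genes with significantly coupled mCH and expression, or the
    top genes by |correlation|). Methylation is sign-reversed (max - value)
    so both modalities vary in the same direction. Each modality is smoothed
    on its own PC-space kNN graph, the two are co-embedded by CCA, restricted
    k-partners are matched, the source modality's missing features are
    imputed, and all cells are jointly reduced (PCA) and Leiden-clustered.

    ``impute_direction`` is "meth" (impute RNA features for methylome cells),
    "rna", or "auto" (impute the smaller dataset into the larger).
    """
    A = np.asarray(meth_features, float)  # methylome cells
    B = np.asarray(rna_features, float)   # transcriptome cells
    if A.shape[1] != B.shape[1] or A.shape[1] == 0:
        raise ValueError("modalities must share a non-empty aligned gene set")
    if not A.any() or not B.any():
        raise ValueError("all-zero feature block")
    if reverse_meth:
        A = A.max() - A

    def _pcs(M: np.ndarray, n: int) -> np.ndarray:
        n = min(n, M.shape[0] - 1, M.shape[1])
        sd = M.std(axis=0)
        scaled = (M - M.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        return PCA(n_components=n, random_state=seed).fit_transform(scaled)

    op_a = build_smoothing_operator(_pcs(A, 50), k=min(k, A.shape[0] - 1), ka=5, p=p_meth)
    op_b = build_smoothing_operator(_pcs(B, 50), k=min(k, B.shape[0] - 1), ka=5, p=p_rna)
    A_s = smooth_features(A, op_a)
    B_s = smooth_features(B, op_b)

    n_cca_eff = min(n_cca, A.shape[0], B.shape[0], A.shape[1])
    emb = cca_coembed(A_s, B_s, n_components=n_cca_eff) if A.shape[0] == B.shape[0] else None
    if emb is None:
        raise ValueError(
            "fuse_datasets currently co-embeds equal-sized cell sets; "
            "subsample or use restricted_k_partners directly for unequal sets"
        )
    coords_a, coords_b = emb.U, emb.V

    if impute_direction == "auto":
        impute_direction = "meth" if A.shape[0] <= B.shape[0] else "rna"
    if impute_direction == "meth":
        graph = restricted_k_partners(coords_a, coords_b, k=min(k, B.shape[0]), z=z,
                                      seed=seed, metric="euclidean")
        imputed = impute_cross_modality(graph, B_s)   # RNA features for meth cells
        stacked = np.vstack([imputed, B_s])
        source = "meth"
    elif impute_direction == "rna":
        graph = restricted_k_partners(coords_b, coords_a, k=min(k, A.shape[0]), z=z,
                                      seed=seed, metric="euclidean")
        imputed = impute_cross_modality(graph, A_s)   # meth features for RNA cells
        stacked = np.vstack([A_s, imputed])
        source = "rna"
    else:
        raise ValueError(f"unknown impute_direction {impute_direction!r}")

    joint = _pcs(stacked, n_pcs)
    g = knn_graph(joint, min(k_graph, joint.shape[0] - 1))
    labels = leiden(g, resolution=resolution, seed=seed)

    umap_coords = None
    if compute_umap:
        import umap

        umap_coords = umap.UMAP(
            n_neighbors=30, min_dist=0.5, random_state=seed
        ).fit_transform(joint)

    n_a = A.shape[0]
    return FusionResult(
        joint_pcs=joint,
        labels_a=labels[:n_a],
        labels_b=labels[n_a:],
        graph=graph,
        coembedding=emb,
        source_modality=source,
        umap_coords=umap_coords,
    )


def transfer_labels(
    graph: PartnerGraph, target_labels: np.ndarray, majority: float = 0.5
) -> np.ndarray:
    """Assign each source cell the label carried by >= ``majority`` of its partners.

    Sources whose best label falls short stay UNASSIGNED. When two labels tie
    at exactly the threshold, the label with more partners across the whole
    graph wins, then lexicographic order.
    """
    target_labels = np.asarray(target_labels)
    if graph.partners.max() >= target_labels.size:
        raise IndexError("partner id outside target label vector")
    global_counts: dict = {}
    for lab in target_labels[graph.partners].ravel():
        global_counts[lab] = global_counts.get(lab, 0) + 1

    out = np.empty(graph.partners.shape[0], dtype=object)
    k = graph.k
    for i, row in enumerate(target_labels[graph.partners]):
        labs, counts = np.unique(row, return_counts=True)
        frac = counts / k
        top = frac.max()
        if top < majority:
            out[i] = UNASSIGNED
            continue
        tied = labs[frac == top]
        if tied.size == 1:
            out[i] = tied[0]
        else:
            out[i] = sorted(tied, key=lambda l: (-global_counts.get(l, 0), str(l)))[0]
    return out
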