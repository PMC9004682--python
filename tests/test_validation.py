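"""CCA co-embedding, k-partners, split scores, CV curves and fusion metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from mcfuse import coupling, synthetic, validation as val


def _coembed_from_truth(normalized_modalities, n_components=20):
    mch, expr, truth = normalized_modalities
    reversed_mch = mch.max() - mch  # align orientation with expression
    return val.cca_coembed(reversed_mch, expr, n_components=n_components), truth


class TestCcaCoembed:
    def test_identical_matrices_self_match(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 30))
        emb = val.cca_coembed(X, X.copy(), n_components=10)
        D = cdist(emb.U, emb.V)
        assert (D.argmin(axis=1) == np.arange(40)).all()

    def test_rank_deficient_input_truncated_with_warning(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((30, 2))
        X = base @ rng.standard_normal((2, 20))  # rank 2
        Y = base @ rng.standard_normal((2, 20))
        with pytest.warns(UserWarning, match="rank"):
            emb = val.cca_coembed(X, Y, n_components=5)
        assert emb.n_components == 2

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 5))
        Y = rng.standard_normal((20, 5))
        X[:, 3] = 0.0
        emb = val.cca_coembed(X, Y, n_components=3)  # no nan anywhere
        assert np.isfinite(emb.U).all() and np.isfinite(emb.V).all()

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            val.cca_coembed(np.ones((5, 3)), np.ones((6, 3)))


class TestCrossModalPartners:
    def test_identical_embeddings_partner_self(self):
        rng = np.random.default_rng(3)
        U = rng.standard_normal((25, 4))
        emb = val.CoEmbedding(U=U, V=U.copy())
        partners = val.cross_modal_partners(emb, k=1)
        assert (partners[:, 0] == np.arange(25)).all()

    def test_collinear_example(self):
        pos = np.array([[0.0], [1.0], [3.0]])
        emb = val.CoEmbedding(U=pos, V=pos.copy())
        partners = val.cross_modal_partners(emb, k=2)
        assert partners[1].tolist() == [1, 0]  # self, then nearer end

    def test_full_ranking(self):
        rng = np.random.default_rng(4)
        U = rng.standard_normal((10, 3))
        emb = val.CoEmbedding(U=U, V=rng.standard_normal((10, 3)))
        partners = val.cross_modal_partners(emb, k=10)
        assert np.array_equal(np.sort(partners, axis=1), np.tile(np.arange(10), (10, 1)))

    def test_k_too_large_rejected(self):
        emb = val.CoEmbedding(U=np.ones((3, 2)), V=np.ones((3, 2)))
        with pytest.raises(ValueError):
            val.cross_modal_partners(emb, k=4)

    def test_brute_force_oracle_equivalence(self):
        """Partner lists match an exhaustive pairwise-distance computation."""
        rng = np.random.default_rng(5)
        U = rng.standard_normal((150, 6))
        V = rng.standard_normal((150, 6))
        emb = val.CoEmbedding(U=U, V=V)
        partners = val.cross_modal_partners(emb, k=7)
        for i in range(150):
            dists = np.array([np.sqrt(((U[i] - V[j]) ** 2).sum()) for j in range(150)])
            expected = np.lexsort((np.arange(150), dists))[:7]
            assert partners[i].tolist() == expected.tolist()


class TestOverSplitting:
    def test_fully_internal_partners_score_zero(self, normalized_modalities):
        emb, truth = _coembed_from_truth(normalized_modalities)
        scores = val.over_splitting_score(emb, truth.cluster_labels)
        assert (scores < 0.05).all()

    def test_artificial_split_scores_half(self, normalized_modalities):
        emb, truth = _coembed_from_truth(normalized_modalities)
        over = []
        for seed in range(5):
            split = synthetic.perturb_labels(truth.cluster_labels, "split", seed=seed)
            scores = val.over_splitting_score(emb, split)
            halves = [c for c in scores.index if c.endswith(("_a", "_b"))]
            over.extend(scores[halves].tolist())
        assert np.allclose(over, 0.5, atol=0.05)

    def test_external_partners_score_one(self):
        # two clusters far apart but modality Y swapped between them:
        # every cell's partners lie in the other cluster
        U = np.vstack([np.zeros((10, 2)), 10 + np.zeros((10, 2))])
        U += 0.01 * np.random.default_rng(0).standard_normal(U.shape)
        V = np.roll(U, 10, axis=0)
        emb = val.CoEmbedding(U=U, V=V)
        labels = np.repeat([0, 1], 10)
        assert (val.over_splitting_score(emb, labels) == 1.0).all()

    def test_invariant_under_relabeling_and_order(self, normalized_modalities):
        emb, truth = _coembed_from_truth(normalized_modalities)
        labels = truth.cluster_labels
        base = val.over_splitting_score(emb, labels).to_numpy()
        renamed = val.over_splitting_score(emb, np.array(["c%d" % l for l in labels]))
        assert np.allclose(base, renamed.to_numpy())


class TestSelfRadii:
    def test_constructed_radius(self):
        # cell 0: self-distance 5; exactly 7 other Y-cells strictly closer
        n = 20
        U = np.zeros((n, 1))
        U[1:] = 100 + 10 * np.arange(n - 1)[:, None]  # park other X-cells far away
        V = np.zeros((n, 1))
        V[0] = 5.0          # own Y-profile at distance 5
        V[1:8] = np.linspace(0.5, 4.5, 7)[:, None]  # 7 closer cross-modal cells
        V[8:] = np.linspace(6, 50, n - 8)[:, None]
        emb = val.CoEmbedding(U=U, V=V)
        assert val.self_radii(emb)[0] == 7

    def test_zero_self_distance_gives_zero(self):
        U = np.arange(5, dtype=float)[:, None]
        emb = val.CoEmbedding(U=U, V=U.copy())
        assert (val.self_radii(emb) == 0).all()

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(6)
        U = rng.standard_normal((120, 5))
        V = rng.standard_normal((120, 5))
        emb = val.CoEmbedding(U=U, V=V)
        radii = val.self_radii(emb)
        for i in range(120):
            dii = np.sqrt(((U[i] - V[i]) ** 2).sum())
            count = sum(
                np.sqrt(((U[i] - V[j]) ** 2).sum()) < dii for j in range(120) if j != i
            )
            assert radii[i] == count

    def test_homogeneous_cluster_radii_uniform(self, normalized_modalities):
        """Within an ideal (per-gene shuffled) cluster, normalized self-radii
        are approximately uniform on [0, 1]."""
        mch, expr, truth = normalized_modalities
        X, Y = val.make_ideal_reference(mch.max() - mch, expr, truth.cluster_labels, seed=0)
        emb = val.cca_coembed(X, Y, n_components=20)
        radii = val.self_radii(emb)
        members = truth.cluster_labels == 0
        rho = radii[members] / members.sum()
        assert stats.kstest(rho, "uniform").pvalue > 0.01


class TestUnderSplitting:
    def test_all_zero_radii(self):
        labels = np.zeros(20, dtype=int)
        scores = val.under_splitting_score(np.zeros(20, dtype=int), labels)
        assert scores[0] == pytest.approx(4.0)

    def test_all_large_radii(self):
        labels = np.zeros(10, dtype=int)
        scores = val.under_splitting_score(np.full(10, 9), labels)
        assert scores[0] == 0.0

    def test_uniform_radii_score_one(self):
        labels = np.zeros(100, dtype=int)
        scores = val.under_splitting_score(np.arange(100), labels)
        assert scores[0] == pytest.approx(1.0, abs=0.05)

    def test_merged_clusters_score_above_one(self, normalized_modalities):
        emb, truth = _coembed_from_truth(normalized_modalities)
        merged = synthetic.perturb_labels(truth.cluster_labels, "merge", seed=0)
        radii = val.self_radii(emb)
        scores = val.under_splitting_score(radii, merged)
        union = [c for c in scores.index if "+" in c]
        assert (scores[union] > 1.0).all()


class TestIdealReference:
    def test_per_gene_cluster_means_preserved(self, normalized_modalities):
        mch, expr, truth = normalized_modalities
        X, Y = val.make_ideal_reference(mch, expr, truth.cluster_labels, seed=1)
        for c in np.unique(truth.cluster_labels):
            m = truth.cluster_labels == c
            assert np.allclose(X[m].mean(axis=0), mch[m].mean(axis=0))
            assert np.allclose(Y[m].mean(axis=0), expr[m].mean(axis=0))

    def test_per_cell_coupling_destroyed(self):
        """Shuffling breaks the pairing of a cell's two profiles: the mean
        cell-wise cross-modal correlation drops toward zero, while per-gene
        cluster-level structure survives."""
        rng = np.random.default_rng(12)
        latent = rng.standard_normal((80, 50))  # shared per-cell signal
        X = latent + 0.5 * rng.standard_normal((80, 50))
        Y = latent + 0.5 * rng.standard_normal((80, 50))
        labels = np.zeros(80, dtype=int)

        def mean_cellwise_corr(A, B):
            return np.mean([stats.pearsonr(A[i], B[i]).statistic for i in range(80)])

        before = mean_cellwise_corr(X, Y)
        Xs, Ys = val.make_ideal_reference(X, Y, labels, seed=2)
        after = mean_cellwise_corr(Xs, Ys)
        assert before > 0.5
        assert abs(after) < 0.2

    def test_seeded_reproducible(self, normalized_modalities):
        mch, expr, truth = normalized_modalities
        a = val.make_ideal_reference(mch, expr, truth.cluster_labels, seed=3)
        b = val.make_ideal_reference(mch, expr, truth.cluster_labels, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestInformationCriteria:
    def test_hand_computed_values(self):
        aic, bic = val.information_criteria(0.5, N=100, d=5, sigma2=1.0)
        assert aic == pytest.approx(0.6)
        assert bic == pytest.approx(0.5 + np.log(100) * 5 / 100)

    def test_penalties_vanish_at_large_n(self):
        aic, bic = val.information_criteria(0.5, N=10**9, d=5, sigma2=1.0)
        assert aic == pytest.approx(0.5, abs=1e-6)
        assert bic == pytest.approx(0.5, abs=1e-6)

    def test_bic_optimum_at_most_aic_optimum(self):
        """On a convex error curve with N > e^2, BIC's heavier penalty puts
        its optimum at no more clusters than AIC's."""
        N, sigma2 = 500, 1.0
        ds = np.arange(1, 30)
        mse = 1.0 / ds + 0.001 * ds  # convex, decreasing then flattening
        aics, bics = zip(*(val.information_criteria(m, N, d, sigma2) for m, d in zip(mse, ds)))
        assert ds[np.argmin(bics)] <= ds[np.argmin(aics)]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            val.information_criteria(0.5, N=0, d=1, sigma2=1.0)
        with pytest.raises(ValueError):
            val.information_criteria(0.5, N=10, d=1, sigma2=0.0)


class TestCvErrorCurve:
    def test_flat_when_eval_constant_across_cells(self, normalized_modalities):
        mch, _, _ = normalized_modalities
        const = np.tile(np.linspace(0, 1, 20), (mch.shape[0], 1))
        curve = val.cv_error_curve(mch, const, resolutions=[0.1, 1.0], n_folds=3, n_seeds=1)
        assert np.allclose(curve.table["test_mse"], 0.0, atol=1e-20)

    def test_test_error_dominates_train_error(self, normalized_modalities):
        mch, expr, _ = normalized_modalities
        curve = val.cv_error_curve(
            mch, expr, resolutions=[0.1, 1.0, 3.0], n_folds=3, n_seeds=2
        )
        g = curve.table.groupby("n_clusters")[["train_mse", "test_mse"]].mean()
        assert (g["test_mse"] >= g["train_mse"]).all()

    def test_optimum_near_planted_cluster_number(self):
        cfg = synthetic.SyntheticConfig(
            n_cells=400, n_genes=150, n_clusters=4, coupled_fraction=1.0, seed=4
        )
        mc, rna, truth = synthetic.generate_multimodal(cfg)
        X = coupling.normalize_gene_mch(mc.mc / np.maximum(mc.cov, 1), truth.global_mch)
        Y = coupling.normalize_expression(rna)
        curve = val.cv_error_curve(
            X, Y, resolutions=[0.02, 0.1, 0.5, 1.0, 3.0, 8.0], n_folds=5, n_seeds=3
        )
        assert abs(curve.optimum("test_mse") - 4) <= 1

    def test_aic_tracks_test_error(self):
        cfg = synthetic.SyntheticConfig(
            n_cells=300, n_genes=100, n_clusters=4, coupled_fraction=1.0, seed=8
        )
        mc, rna, truth = synthetic.generate_multimodal(cfg)
        X = coupling.normalize_gene_mch(mc.mc / np.maximum(mc.cov, 1), truth.global_mch)
        Y = coupling.normalize_expression(rna)
        curve = val.cv_error_curve(
            X, Y, resolutions=[0.02, 0.1, 0.5, 1.0, 3.0, 8.0], n_folds=5, n_seeds=3
        )
        g = curve.table.groupby("n_clusters")[["aic", "test_mse"]].mean()
        if len(g) >= 3:
            r = stats.pearsonr(g["aic"], g["test_mse"]).statistic
            assert r > 0.8


class TestEvaluateFusion:
    def _paired_coords(self, rng, n=60, sep=20.0):
        base = rng.standard_normal((n, 4))
        return np.vstack([base, base + 0.01 * rng.standard_normal((n, 4))])

    def test_perfect_fusion(self):
        rng = np.random.default_rng(7)
        blobs = np.vstack([rng.standard_normal((20, 4)) + 10 * i for i in range(3)])
        coords = np.vstack([blobs, blobs])  # identical profiles per cell
        pairs = np.column_stack([np.arange(60), np.arange(60) + 60])
        m = val.evaluate_fusion(coords, pairs, target_n_coclusters=3, k_neighbors=10)
        assert m.misfusion_ratio == 0.0
        assert m.cocluster_accuracy == 1.0
        assert (m.normalized_self_radius <= 2 / 120).all()

    def test_randomized_coordinates_misfuse(self):
        rng = np.random.default_rng(8)
        coords = rng.standard_normal((200, 4))
        pairs = np.column_stack([np.arange(100), np.arange(100) + 100])
        m = val.evaluate_fusion(coords, pairs, k_neighbors=10)
        # uniform ranks: expected mis-fusion ~ 1 - 0.3
        assert abs(m.misfusion_ratio - 0.7) < 0.12

    def test_threshold_one_never_misfused(self):
        rng = np.random.default_rng(9)
        coords = rng.standard_normal((40, 3))
        pairs = np.column_stack([np.arange(20), np.arange(20) + 20])
        m = val.evaluate_fusion(coords, pairs, misfusion_threshold=1.0, k_neighbors=5)
        assert m.misfusion_ratio == 0.0

    def test_target_cocluster_count_reached(self):
        rng = np.random.default_rng(10)
        blobs = np.vstack([rng.standard_normal((40, 3)) + 8 * i for i in range(3)])
        coords = np.vstack([blobs, blobs + 0.01])
        pairs = np.column_stack([np.arange(120), np.arange(120) + 120])
        m = val.evaluate_fusion(coords, pairs, target_n_coclusters=3, k_neighbors=10)
        assert m.n_coclusters == 3


class TestOverlapScore:
    def test_identical_partitions_identity_matrix(self):
        labels = np.repeat(np.arange(4), 30)
        score = val.overlap_score(labels, labels, labels)
        assert np.allclose(score.to_numpy(), np.eye(4))

    def test_never_cocluster_scores_zero(self):
        # b is a's complement: matched pairs never share a co-cluster
        a = np.array([0, 0, 1, 1])
        b = np.array([1, 1, 0, 0])
        cc = np.array([0, 0, 1, 1])
        score = val.overlap_score(a, b, cc)
        assert score.loc[0, 0] == 0.0 and score.loc[1, 1] == 0.0
        assert score.loc[0, 1] == 1.0 and score.loc[1, 0] == 1.0

    def test_partial_overlap_min_rule(self):
        # cluster a fully in co-cluster g; cluster b half in g -> min = 0.5
        a = np.array([0, 0])
        b = np.array([0, 0, 0, 0])
        cc = np.array([0, 0, 0, 0, 1, 1])  # a-cells then b-cells
        score = val.overlap_score(a, b, cc)
        assert score.loc[0, 0] == pytest.approx(0.5)
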