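"""KL distances, entropy calibration, t-SNE and re-embedding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posturemap import embedding as emb
from posturemap.embedding import (
    _row_entropy_bits,
    calibrate_transitions,
    kl_distance,
    pairwise_kl,
    reembed_points,
    select_training_set,
    tsne_embed,
)


class TestKL:
    def test_hand_evaluated_example(self):
        # 0.5 log2(2) + 0.5 log2(2/3) = 1 - 0.5 log2 3 = 0.20752...
        assert kl_distance([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
            0.2075187, abs=1e-6
        )

    def test_identity_and_asymmetry(self):
        p = np.array([0.2, 0.3, 0.5])
        q = np.array([0.5, 0.25, 0.25])
        assert kl_distance(p, p) == 0.0
        assert kl_distance(p, q) != kl_distance(q, p)

    def test_zero_handling(self):
        assert kl_distance([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)
        # q=0 where p>0 hits the 1e-12 floor, stays finite
        assert np.isfinite(kl_distance([0.5, 0.5], [1.0, 0.0]))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            kl_distance([0.5, 0.6], [0.5, 0.5])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_nonnegative_and_matches_scalar(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((4, 6)) + 1e-3
        P /= P.sum(axis=1, keepdims=True)
        D = pairwise_kl(P)
        assert np.all(D >= 0)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-10)
        assert D[1, 2] == pytest.approx(kl_distance(P[1], P[2]), abs=1e-9)


class TestCalibration:
    def test_equidistant_points_exact(self):
        n = 33
        D = np.ones((n, n)) - np.eye(n)
        tm = calibrate_transitions(D, H=5.0)
        np.testing.assert_allclose(tm.P + np.eye(n) / 32, 1.0 / 32, atol=1e-12)
        np.testing.assert_allclose(_row_entropy_bits(tm.P), 5.0, atol=1e-12)
        assert tm.perplexity == 32.0

    def test_random_matrix_rows_calibrated(self):
        rng = np.random.default_rng(3)
        for H in (3.0, 5.0):
            A = rng.random((80, 80))
            D = A + A.T
            np.fill_diagonal(D, 0.0)
            tm = calibrate_transitions(D, H=H)
            np.testing.assert_allclose(tm.P.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(np.diag(tm.P), 0.0)
            np.testing.assert_allclose(_row_entropy_bits(tm.P), H, atol=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            calibrate_transitions(np.ones((3, 4)))
        D = np.ones((4, 4))
        with pytest.raises(ValueError):
            calibrate_transitions(D)  # nonzero diagonal


class TestTsne:
    def test_single_point(self):
        model = tsne_embed(np.array([[0.5, 0.5]]), seed=0)
        np.testing.assert_array_equal(model.train_coords, np.zeros((1, 2)))

    def test_clusters_preserved(self, cluster_spectra):
        X, labels = cluster_spectra
        model = tsne_embed(X, H=5.0, seed=1, n_iter=500)
        from sklearn.model_selection import cross_val_score
        from sklearn.neighbors import KNeighborsClassifier

        acc = cross_val_score(
            KNeighborsClassifier(1), model.train_coords, labels, cv=5
        ).mean()
        assert acc >= 0.99

    def test_seed_determinism_bitwise(self, cluster_spectra):
        X, _ = cluster_spectra
        m1 = tsne_embed(X[:90], H=4.0, seed=7, n_iter=300)
        m2 = tsne_embed(X[:90], H=4.0, seed=7, n_iter=300)
        assert np.array_equal(m1.train_coords, m2.train_coords)
        assert m1.final_cost == m2.final_cost

    def test_duplicated_points_coincide(self, cluster_spectra):
        X, _ = cluster_spectra
        Xd = np.vstack([X[:60], X[:60]])
        model = tsne_embed(Xd, H=4.0, seed=2, n_iter=500)
        Y = model.train_coords
        d_dup = np.linalg.norm(Y[:60] - Y[60:120], axis=1)
        span = np.linalg.norm(Y.max(axis=0) - Y.min(axis=0))
        assert np.median(d_dup) < 0.05 * span

    def test_local_neighbourhoods_preserved(self):
        # three clusters, each with smooth internal (arc) structure so the
        # 10-NN sets are meaningful below the cluster scale
        rng = np.random.default_rng(7)

        def arc(c0, c1, n=100, dim=30):
            t = np.linspace(0, 1, n)
            base = np.full((n, dim), 0.01)
            base[:, c0] += 1.0 - t
            base[:, c1] += t
            X = base + np.abs(rng.normal(0, 0.01, (n, dim)))
            return X / X.sum(axis=1, keepdims=True)

        X = np.vstack([arc(3, 7), arc(14, 18), arc(24, 28)])
        model = tsne_embed(X, H=5.0, seed=3, n_iter=500)
        D_hi = pairwise_kl(X)
        np.fill_diagonal(D_hi, np.inf)
        Y = model.train_coords
        D_lo = np.linalg.norm(Y[:, None] - Y[None], axis=2)
        np.fill_diagonal(D_lo, np.inf)
        overlaps = []
        for i in range(len(X)):
            hi = set(np.argsort(D_hi[i])[:10])
            lo = set(np.argsort(D_lo[i])[:10])
            overlaps.append(len(hi & lo) / 10)
        assert np.mean(overlaps) >= 0.5

    def test_agrees_with_reference_implementation(self, cluster_spectra):
        """Independent route: sklearn's exact t-SNE on the same KL
        distances separates the clusters the same way."""
        from sklearn.manifold import TSNE
        from sklearn.metrics import adjusted_rand_score
        from sklearn.cluster import KMeans

        X, labels = cluster_spectra
        D = pairwise_kl(X)
        D = (D + D.T) / 2  # sklearn requires symmetric precomputed distances
        ref = TSNE(
            metric="precomputed", perplexity=32, init="random",
            random_state=0, method="exact",
        ).fit_transform(D)
        ours = tsne_embed(X, H=5.0, seed=1, n_iter=500).train_coords
        ari_ref = adjusted_rand_score(
            labels, KMeans(3, n_init=5, random_state=0).fit_predict(ref)
        )
        ari_ours = adjusted_rand_score(
            labels, KMeans(3, n_init=5, random_state=0).fit_predict(ours)
        )
        assert ari_ref > 0.95 and ari_ours > 0.95


class TestTrainingSelection:
    def test_equal_movie_quotas(self):
        rng = np.random.default_rng(0)
        movies = [rng.random((700, 5)) for _ in range(59)]
        for m in movies:
            m /= m.sum(axis=1, keepdims=True)
        picks = select_training_set(movies, 35_000, seed=0)
        sizes = {len(p) for p in picks}
        assert sizes <= {593, 594}
        assert sum(len(p) for p in picks) == 35_000

    def test_single_movie(self):
        rng = np.random.default_rng(1)
        m = rng.random((200, 4))
        m /= m.sum(axis=1, keepdims=True)
        (picks,) = select_training_set([m], 50, seed=0)
        assert len(picks) == 50
        assert len(np.unique(picks)) == 50

    def test_rare_state_enriched(self):
        rng = np.random.default_rng(2)
        common = np.abs(rng.normal(1.0, 0.02, (9900, 8)))
        rare = np.abs(rng.normal(1.0, 0.02, (100, 8)))
        rare[:, 0] += 5.0  # distinct region of feature space
        X = np.vstack([common, rare])
        X /= X.sum(axis=1, keepdims=True)
        (picks,) = select_training_set([X], 1000, seed=0)
        rare_frac = np.mean(picks >= 9900)
        assert rare_frac >= 5 * (100 / 10_000)

    def test_too_many_requested(self):
        with pytest.raises(ValueError):
            select_training_set([np.full((10, 2), 0.5)], 11)


class TestReembed:
    def test_training_point_lands_on_itself(self, cluster_spectra):
        from scipy.spatial import cKDTree

        X, _ = cluster_spectra
        model = tsne_embed(X, H=5.0, seed=4, n_iter=400)
        z = reembed_points(X[:10], model)
        # a duplicated training point re-embeds within the local point
        # spacing of its own coordinate (within a dense cluster, several
        # training points are statistically interchangeable)
        spacing = np.median(
            cKDTree(model.train_coords).query(model.train_coords, k=2)[0][:, 1]
        )
        d_self = np.linalg.norm(z - model.train_coords[:10], axis=1)
        assert np.all(d_self < 3 * spacing)
        D = np.linalg.norm(z[:, None] - model.train_coords[None], axis=2)
        assert (D.argmin(axis=1) == np.arange(10)).sum() >= 8

    def test_symmetric_point_on_bisector(self):
        # exact symmetry oracle: two training points, a new point whose
        # spectrum is the exact midpoint -> equal transition probabilities
        # -> the objective is minimized on the perpendicular bisector
        from posturemap.embedding import EmbeddingModel

        a = np.array([0.8, 0.1, 0.1])
        b = np.array([0.1, 0.8, 0.1])
        model = EmbeddingModel(
            train_features=np.vstack([a, b]),
            train_coords=np.array([[-5.0, 0.0], [5.0, 0.0]]),
            target_entropy=1.0,
            seed=0,
            n_iter=0,
            final_cost=0.0,
        )
        mid = 0.5 * (a + b)
        z = reembed_points(mid[None], model, n_iter=400)[0]
        assert abs(z[0]) < 1e-3  # on the bisector x = 0

    def test_heldout_cluster_members_rejoin_cluster(self, cluster_spectra):
        X, labels = cluster_spectra
        train_idx = np.concatenate([np.arange(s, s + 80) for s in (0, 100, 200)])
        test_idx = np.setdiff1d(np.arange(300), train_idx)
        model = tsne_embed(X[train_idx], H=5.0, seed=6, n_iter=400)
        z = reembed_points(X[test_idx], model)
        from sklearn.neighbors import KNeighborsClassifier

        clf = KNeighborsClassifier(5).fit(model.train_coords, labels[train_idx])
        acc = (clf.predict(z) == labels[test_idx]).mean()
        assert acc >= 0.95

    def test_dimension_mismatch(self, cluster_spectra):
        X, _ = cluster_spectra
        model = tsne_embed(X[:50], H=4.0, seed=0, n_iter=200)
        with pytest.raises(ValueError):
            reembed_points(np.full((2, 5), 0.2), model)
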