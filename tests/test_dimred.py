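"""Inertia/co-inertia identities, MCIA structure and optimality, PCA and
t-SNE embeddings."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from morphomcia.dimred import (
    MCIAConfig,
    _prepare_blocks,
    coinertia,
    inertia,
    mcia_fit,
    mcia_objective,
    pca_embed,
    summed_center_distances,
    tsne_embed,
)
from morphomcia.shape_features import FeatureMatrix, standardize

rng = np.random.default_rng(123)


def _fm(X, organ="x", standardized=False):
    return FeatureMatrix(
        X=X,
        feature_names=[f"f{i}" for i in range(X.shape[0])],
        organ=organ,
        standardized=standardized,
    )


def _std_block(d, n, organ):
    return standardize(_fm(rng.normal(size=(d, n)), organ))


class TestInertia:
    def test_standardized_equals_feature_count(self):
        z = _std_block(37, 9, "a")
        assert inertia(z) == pytest.approx(37.0, abs=1e-8)

    def test_zero_matrix(self):
        assert inertia(np.zeros((4, 6))) == 0.0

    def test_double_sum_oracle(self):
        X = rng.normal(size=(5, 8))
        X -= X.mean(axis=1, keepdims=True)
        w = rng.random(8)
        w /= w.sum()
        Q = np.eye(5) * rng.uniform(0.5, 2, 5)
        brute = sum(
            w[i] * sum(Q[f, f] * X[f, i] ** 2 for f in range(5))
            for i in range(8)
        )
        assert inertia(X, w, Q) == pytest.approx(brute, abs=1e-10)

    def test_weight_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            inertia(np.zeros((3, 4)), w=np.ones(5) / 5)


class TestCoinertia:
    def test_self_coinertia_trace_square(self):
        X = rng.normal(size=(6, 10))
        X -= X.mean(axis=1, keepdims=True)
        w = np.full(10, 0.1)
        A = (X * w) @ X.T
        assert coinertia(X, X, w) == pytest.approx(np.trace(A @ A), abs=1e-10)
        assert coinertia(X, X, w) >= 0

    def test_orthogonal_blocks_zero(self):
        # Y built in the orthogonal complement of X's row space under W
        X = rng.normal(size=(3, 8))
        X -= X.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(X.T)
        Y = rng.normal(size=(2, 8))
        Y = Y - (Y @ q) @ q.T
        assert coinertia(X, Y, np.full(8, 1 / 8)) == pytest.approx(0.0, abs=1e-10)

    def test_eigenbasis_double_sum_oracle(self):
        X = rng.normal(size=(3, 4))
        Y = rng.normal(size=(2, 4))
        X -= X.mean(axis=1, keepdims=True)
        Y -= Y.mean(axis=1, keepdims=True)
        w = np.full(4, 0.25)
        # complete orthonormal eigenbases of the two scatter matrices
        _, U = np.linalg.eigh((X * w) @ X.T)
        _, V = np.linalg.eigh((Y * w) @ Y.T)
        M = (X * w) @ Y.T
        brute = sum(
            (U[:, k] @ M @ V[:, j]) ** 2
            for k in range(3)
            for j in range(2)
        )
        assert coinertia(X, Y, w) == pytest.approx(brute, abs=1e-10)

    def test_symmetry(self):
        X = rng.normal(size=(4, 6))
        Y = rng.normal(size=(3, 6))
        assert coinertia(X, Y) == pytest.approx(coinertia(Y, X), abs=1e-12)

    def test_sample_mismatch_errors(self):
        with pytest.raises(ValueError):
            coinertia(np.zeros((2, 4)), np.zeros((2, 5)))


class TestMCIA:
    def test_identical_blocks_symmetry(self, standardized_blocks):
        b = standardized_blocks[0]
        copies = [
            FeatureMatrix(
                X=b.X.copy(), feature_names=b.feature_names,
                organ=f"copy{i}", standardized=True,
            )
            for i in range(3)
        ]
        res = mcia_fit(copies, MCIAConfig(n_axes=2))
        assert np.allclose(res.block_scores[0], res.block_scores[1])
        assert np.allclose(res.block_scores[0], res.block_scores[2])
        assert np.allclose(res.centers, res.block_scores[0])
        assert np.allclose(
            res.pseudo_eigenvalues[0], res.pseudo_eigenvalues[1]
        )
        assert np.allclose(summed_center_distances(res), 0.0)

    def test_pca_matches_mcia_on_copies(self, standardized_blocks):
        # with S copies of one block, each MCIA block loading is that
        # block's principal axis (up to sign)
        b = standardized_blocks[0]
        copies = [
            FeatureMatrix(X=b.X.copy(), feature_names=b.feature_names,
                          organ=f"c{i}", standardized=True)
            for i in range(2)
        ]
        res = mcia_fit(copies, MCIAConfig(n_axes=1, block_scaling="none"))
        Xc = b.X - b.X.mean(axis=1, keepdims=True)
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        cos = abs(res.loadings[0][:, 0] @ U[:, 0])
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_axis1_monte_carlo_optimality(self, standardized_blocks):
        blocks = standardized_blocks[:2]
        cfg = MCIAConfig(n_axes=1)
        res = mcia_fit(blocks, cfg)
        mats, _, n, _ = _prepare_blocks(blocks, cfg)
        w = res.weights
        best_random = 0.0
        for _ in range(300):
            us = []
            for m in mats:
                u = rng.normal(size=m.shape[0])
                us.append(u / np.linalg.norm(u))
            h = rng.normal(size=n)
            h = h / np.sqrt(np.sum(w * h * h))
            best_random = max(best_random, mcia_objective(mats, us, h, w))
        assert res.eigenvalues[0] >= best_random

    def test_row_permuted_block_same_axis(self, standardized_blocks):
        b1, b2 = standardized_blocks[:2]
        perm = rng.permutation(b1.d)
        b1p = FeatureMatrix(
            X=b1.X[perm], feature_names=[b1.feature_names[i] for i in perm],
            organ="perm", standardized=True,
        )
        res_a = mcia_fit([b1, b2], MCIAConfig(n_axes=1))
        res_b = mcia_fit([b1p, b2], MCIAConfig(n_axes=1))
        assert res_a.eigenvalues[0] == pytest.approx(res_b.eigenvalues[0], abs=1e-10)
        cos = abs(res_a.synthetic_axes[:, 0] @ (res_a.weights * res_b.synthetic_axes[:, 0]))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_axes_w_orthogonal_and_objectives_decreasing(self, standardized_blocks):
        res = mcia_fit(standardized_blocks, MCIAConfig(n_axes=4))
        H, w = res.synthetic_axes, res.weights
        G = H.T @ (w[:, None] * H)
        assert np.abs(G - np.eye(res.n_axes)).max() < 1e-8
        assert np.all(np.diff(res.eigenvalues) <= 1e-10)
        assert np.allclose(
            res.pseudo_eigenvalues.sum(axis=0), res.eigenvalues, atol=1e-10
        )

    def test_s2_top_eigenvalue(self, standardized_blocks):
        blocks = standardized_blocks[:2]
        cfg = MCIAConfig(n_axes=1)
        res = mcia_fit(blocks, cfg)
        mats, _, n, _ = _prepare_blocks(blocks, cfg)
        w = res.weights
        sw = np.sqrt(w)
        K = sum((m * sw).T @ (m * sw) for m in mats)
        assert res.eigenvalues[0] == pytest.approx(
            np.linalg.eigvalsh(K)[-1], abs=1e-10
        )

    def test_single_block_errors(self, standardized_blocks):
        with pytest.raises(ValueError, match="at least 2"):
            mcia_fit(standardized_blocks[:1])

    def test_unstandardized_block_errors(self):
        raw = _fm(rng.normal(size=(5, 8)), "raw")
        with pytest.raises(ValueError, match="not standardized"):
            mcia_fit([raw, raw])


class TestSummedCenterDistances:
    def test_toy_hand_arithmetic(self, standardized_blocks):
        res = mcia_fit(standardized_blocks[:2], MCIAConfig(n_axes=2))
        res.centers = np.zeros_like(res.centers)
        res.block_scores[0] = np.tile([3.0, 4.0], (len(res.centers), 1))
        res.block_scores[1] = np.zeros_like(res.block_scores[1])
        assert np.allclose(summed_center_distances(res), 5.0)

    def test_non_negative_and_rotation_invariant(self, standardized_blocks):
        res = mcia_fit(standardized_blocks, MCIAConfig(n_axes=2))
        d0 = summed_center_distances(res)
        assert np.all(d0 >= 0)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        res.centers = res.centers @ R.T
        res.block_scores = [s @ R.T for s in res.block_scores]
        assert np.allclose(summed_center_distances(res), d0, atol=1e-10)


class TestPCA:
    def test_duplicated_individual_same_scores(self):
        X = rng.normal(size=(12, 6))
        X[:, 3] = X[:, 1]
        emb = pca_embed(_fm(X))
        assert np.allclose(emb.coords[1], emb.coords[3])

    def test_gram_matrix_oracle(self, standardized_blocks):
        b = standardized_blocks[1]
        emb = pca_embed(b)
        Xc = b.X - b.X.mean(axis=1, keepdims=True)
        lam = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        assert np.allclose((emb.coords**2).sum(axis=0), lam[:2], atol=1e-8)

    def test_variance_explained_monotone(self, standardized_blocks):
        emb = pca_embed(standardized_blocks[2], n_axes=4)
        ve = emb.variance_explained
        assert np.all(np.diff(ve) <= 1e-12)
        assert ve.sum() <= 1 + 1e-12

    def test_too_few_individuals_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            pca_embed(_fm(rng.normal(size=(5, 2))))


def _tsne_kl(X, emb, perplexity):
    """Independent KL(P||Q) at the given perplexity (binary-searched
    Gaussian bandwidths; Student-t low-dimensional affinities)."""
    D = squareform(pdist(X, "sqeuclidean"))
    n = len(X)
    P = np.zeros((n, n))
    target = np.log(perplexity)
    for i in range(n):
        lo, hi = 1e-12, 1e12
        for _ in range(80):
            beta = np.sqrt(lo * hi)
            p = np.exp(-D[i] * beta)
            p[i] = 0
            s = p.sum()
            p = p / s if s > 0 else p
            mask = p > 0
            H = -np.sum(p[mask] * np.log(p[mask]))
            if H > target:
                lo = beta
            else:
                hi = beta
        P[i] = p
    P = (P + P.T) / (2 * n)
    Dq = squareform(pdist(emb, "sqeuclidean"))
    Q = 1.0 / (1.0 + Dq)
    np.fill_diagonal(Q, 0)
    Q /= Q.sum()
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))


class TestTSNE:
    def test_deterministic_given_seed(self, standardized_blocks):
        b = standardized_blocks[0]
        a = tsne_embed(b, seed=0)
        c = tsne_embed(b, seed=0)
        assert np.array_equal(a.coords, c.coords)

    def test_kl_improves_after_exaggeration_phase(self):
        fm = standardize(_fm(rng.normal(size=(8, 40))))
        perp = 5.0
        early = tsne_embed(fm, perplexity=perp, seed=1, iters=250)
        full = tsne_embed(fm, perplexity=perp, seed=1, iters=1000)
        Xs = fm.X.T
        assert _tsne_kl(Xs, full.coords, perp) <= _tsne_kl(Xs, early.coords, perp) + 1e-9

    def test_separates_two_clusters(self):
        from sklearn.linear_model import LogisticRegression

        X = np.vstack(
            [rng.normal(size=(20, 5)), rng.normal(size=(20, 5)) + 12.0]
        ).T
        emb = tsne_embed(standardize(_fm(X)), seed=0)
        y = np.repeat([0, 1], 20)
        acc = LogisticRegression().fit(emb.coords, y).score(emb.coords, y)
        assert acc == 1.0

    def test_infeasible_perplexity_errors(self, standardized_blocks):
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(standardized_blocks[0], perplexity=10.0)
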