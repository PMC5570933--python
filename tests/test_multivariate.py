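"""Scaling, HCA, PCA, PLS-DA, OPLS-DA against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA
from sklearn.metrics import adjusted_rand_score

from transomics import (
    OPLSDA,
    PCA,
    PLSDA,
    HierarchicalClustering,
    autoscale,
    hca,
    oplsda,
    pca,
    plsda,
    zscore_features,
)
from transomics.multivariate import encode_classes


class TestZscore:
    def test_closed_form(self):
        out = zscore_features(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert np.allclose(out.values[0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_row_becomes_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_features(pd.DataFrame([[5.0, 5.0, 5.0]]))
        assert np.all(out.values == 0)

    def test_idempotent_for_non_constant_rows(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 8)))
        once = zscore_features(df)
        twice = zscore_features(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)


class TestPCA:
    def test_rank1_data_pc1_fraction_1(self, rng):
        u = rng.normal(size=(10, 1))
        v = rng.normal(size=(1, 6))
        m = pca(u @ v)
        assert m.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_1(self, rng):
        m = pca(rng.normal(size=(12, 5)))
        assert m.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-12)

    def test_loadings_match_covariance_eigenvectors_5x4(self, rng):
        X = rng.normal(size=(5, 4))
        m = pca(X)
        C = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        for k in range(4):
            dot = abs(evecs[:, k] @ m.loadings_[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_reconstruction_all_components(self, rng):
        X = rng.normal(size=(8, 5))
        m = pca(X)
        rec = m.scores_ @ m.loadings_.T + m.mean_
        assert np.linalg.norm(rec - X) / np.linalg.norm(X - X.mean(0)) < 1e-8

    def test_matches_sklearn_variance_ratio(self, rng):
        X = rng.normal(size=(20, 7))
        assert np.allclose(
            pca(X).explained_variance_ratio_,
            SkPCA().fit(X).explained_variance_ratio_,
            atol=1e-10,
        )

    def test_sign_convention_largest_loading_positive(self, rng):
        m = pca(rng.normal(size=(9, 4)))
        for k in range(m.loadings_.shape[1]):
            j = np.argmax(np.abs(m.loadings_[:, k]))
            assert m.loadings_[j, k] > 0

    def test_sklearn_protocol(self):
        est = PCA(n_components=2)
        assert est.get_params()["n_components"] == 2
        est.set_params(n_components=3)
        assert est.n_components == 3


def separated_two_class(rng, gap=8.0, n=10, p=12):
    y = np.array(["fast"] * n + ["feed"] * n)
    X = rng.normal(size=(2 * n, p))
    X[y == "feed", 0] += gap
    return X, y


class TestPLSDA:
    def test_separated_classes_zero_score_overlap(self, rng):
        X, y = separated_two_class(rng)
        m = plsda(X, y)
        s_a = m.x_scores_[y == "fast", 0]
        s_b = m.x_scores_[y == "feed", 0]
        assert max(s_a.max(), s_b.max()) > min(s_a.min(), s_b.min())  # sanity
        assert s_a.max() < s_b.min() or s_b.max() < s_a.min()

    def test_first_weight_is_dominant_singular_vector_of_XtY(self, rng):
        X, y = separated_two_class(rng)
        m = plsda(X, y, n_components=1)
        Y, _ = encode_classes(y)
        Xc = X - X.mean(0)
        u = np.linalg.svd(Xc.T @ Y, full_matrices=False)[0][:, 0]
        assert np.abs(np.abs(u) - np.abs(m.x_weights_[:, 0])).max() < 1e-6

    def test_scores_mutually_orthogonal(self, rng):
        X, y = separated_two_class(rng)
        m = plsda(X, y, n_components=3)
        T = m.x_scores_
        for i, j in itertools.combinations(range(T.shape[1]), 2):
            assert abs(T[:, i] @ T[:, j]) < 1e-8 * np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j])

    def test_permuted_labels_separate_less(self, rng):
        """Class-mean score separation beats >= 95% of 200 label permutations."""
        X, y = separated_two_class(rng, gap=4.0, n=8, p=10)

        def sep(labels):
            m = plsda(X, labels, n_components=1)
            s = m.x_scores_[:, 0]
            return abs(s[labels == labels[0]].mean() - s[labels != labels[0]].mean())

        observed = sep(y)
        beaten = sum(sep(rng.permutation(y)) < observed for _ in range(200))
        assert beaten >= 190

    def test_class_validation(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError, match="two classes"):
            plsda(X, ["a"] * 6)
        with pytest.raises(ValueError, match="at least two samples"):
            plsda(X, ["a", "a", "a", "a", "a", "b"])

    def test_predict_recovers_training_labels_when_separated(self, rng):
        X, y = separated_two_class(rng)
        assert (plsda(X, y).predict(X) == y).all()

    def test_three_class_encoding(self, rng):
        y = np.repeat(["a", "b", "c"], 6)
        X = rng.normal(size=(18, 5))
        X[y == "a", 0] += 6
        X[y == "b", 1] += 6
        m = plsda(X, y, n_components=2)
        assert m.x_scores_.shape == (18, 2)
        assert m.y_loadings_.shape[0] == 3


class TestOPLSDA:
    def test_n_ortho_0_equals_plsda_component_1(self, rng):
        X, y = separated_two_class(rng)
        t_opls = oplsda(X, y, n_ortho=0).t_scores_
        t_pls = plsda(X, y, n_components=1).x_scores_[:, 0]
        assert np.abs(t_opls - t_pls).max() < 1e-8

    def test_orthogonal_scores_uncorrelated_with_class(self, rng):
        X, y = separated_two_class(rng)
        m = oplsda(X, y, n_ortho=2)
        yv = m.y_
        for k in range(m.ortho_scores_.shape[1]):
            r = np.corrcoef(m.ortho_scores_[:, k], yv)[0, 1]
            assert abs(r) < 1e-8

    def test_confounder_removal_improves_separation(self, rng):
        """A strong class-orthogonal confounder degrades PLS-DA comp 1; OSC
        filtering restores the class axis."""
        n, p = 12, 10
        y = np.array(["a"] * n + ["b"] * n)
        X = rng.normal(scale=0.3, size=(2 * n, p))
        X[y == "b", 0] += 2.0  # class signal
        conf = rng.normal(size=2 * n)
        conf -= conf.mean()
        # orthogonalize confounder against the class vector, then amplify
        yv = np.where(y == "b", 1.0, -1.0)
        conf -= (conf @ yv) / (yv @ yv) * yv
        X[:, 1] += 12.0 * conf

        def separation(t):
            sa, sb = t[y == "a"], t[y == "b"]
            pooled = np.sqrt(0.5 * (sa.var(ddof=1) + sb.var(ddof=1)))
            return abs(sa.mean() - sb.mean()) / pooled

        sep_pls = separation(plsda(X, y, n_components=1).x_scores_[:, 0])
        sep_opls = separation(oplsda(X, y, n_ortho=1).t_scores_)
        assert sep_opls > sep_pls

    def test_three_classes_rejected(self, rng):
        X = rng.normal(size=(9, 4))
        with pytest.raises(ValueError, match="two classes"):
            oplsda(X, np.repeat(["a", "b", "c"], 3))

    def test_transform_reproduces_training_scores(self, rng):
        X, y = separated_two_class(rng)
        m = oplsda(X, y, n_ortho=1)
        assert np.allclose(m.transform(X)[:, 0], m.t_scores_, atol=1e-10)


def brute_force_complete_linkage(points):
    """Naive agglomeration oracle for a handful of points."""
    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = max(
                np.linalg.norm(points[i] - points[j]) for i in a for j in b
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append(d)
    return merges


class TestHCA:
    def test_identical_rows_merge_at_height_zero(self):
        res = hca(np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]]))
        assert res.linkage[0, 2] == 0.0

    def test_planted_clusters_perfect_ari(self, rng):
        centers = np.array([[0.0] * 6, [50.0] * 6, [-50.0] * 6])
        labels = np.repeat([0, 1, 2], 12)
        X = centers[labels] + rng.normal(size=(36, 6))  # centers 50 sd apart
        res = hca(X)
        assert adjusted_rand_score(labels, res.cut(3)) == 1.0

    def test_merge_heights_match_brute_force_on_4_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [10.5, 4.0]])
        res = hca(pts)
        assert np.allclose(sorted(res.linkage[:, 2]), sorted(brute_force_complete_linkage(pts)))

    def test_heights_non_decreasing_and_leaf_order_permutation(self, rng):
        X = rng.normal(size=(15, 4))
        res = hca(X)
        h = res.linkage[:, 2]
        assert (np.diff(h) >= -1e-12).all()
        assert sorted(res.leaf_order) == list(range(15))

    def test_row_permutation_gives_same_heights(self, rng):
        X = rng.normal(size=(12, 5))
        perm = rng.permutation(12)
        assert np.allclose(
            np.sort(hca(X).linkage[:, 2]), np.sort(hca(X[perm]).linkage[:, 2])
        )

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            HierarchicalClustering().fit(np.ones((1, 3)))

    def test_newick_export_parses_with_all_leaves(self, rng):
        import dendropy

        X = rng.normal(size=(7, 3))
        nwk = hca(X).to_newick([f"g{i}" for i in range(7)])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 7


def test_autoscale_unit_variance(rng):
    X = rng.normal(loc=3, scale=5, size=(30, 4))
    A = autoscale(X)
    assert np.allclose(A.mean(0), 0, atol=1e-12)
    assert np.allclose(A.std(0), 1, atol=1e-12)
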