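"""Clustering stage: contrast construction, forest and OOB proximity
contracts, classical MDS, average-linkage cuts, validity indices against
brute-force oracles, and composite model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import gmpatterns as g
from gmpatterns import cluster as gc
from tests.conftest import two_blob_features


# ---------------------------------------------------------------- oracles

def dunn_oracle(D, labels):
    labels = np.asarray(labels)
    n = len(labels)
    between, within = np.inf, 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                within = max(within, D[i, j])
            else:
                between = min(between, D[i, j])
    return between / within


def ch_oracle(X, labels):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, k = len(X), len(set(labels))
    grand = X.mean(axis=0)
    bss = wss = 0.0
    for u in set(labels):
        grp = X[labels == u]
        bss += len(grp) * np.sum((grp.mean(axis=0) - grand) ** 2)
        wss += np.sum((grp - grp.mean(axis=0)) ** 2)
    return (bss / (k - 1)) / (wss / (n - k))


def random_instance(rng, n=12, k=3):
    X = rng.normal(size=(n, 2))
    labels = rng.integers(1, k + 1, size=n)
    while len(set(labels)) < 2:
        labels = rng.integers(1, k + 1, size=n)
    return X, labels


# ---------------------------------------------------------------- tests

class TestContrastData:
    def test_values_come_from_observed_support(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        C = g.generate_contrast_data(X, 0)
        for j, col in enumerate("abc"):
            assert set(np.round(C[:, j], 12)) <= set(np.round(X[col], 12))

    def test_marginal_means_preserved(self, rng):
        X = rng.normal(5.0, 2.0, size=(1000, 4))
        C = g.generate_contrast_data(X, 1)
        se = 2.0 / np.sqrt(1000)
        assert np.all(np.abs(C.mean(0) - X.mean(0)) < 3 * se)

    def test_dependence_destroyed(self, rng):
        a = rng.normal(size=1000)
        X = np.column_stack([a, a])  # perfectly correlated columns
        C = g.generate_contrast_data(X, 2)
        assert abs(np.corrcoef(C.T)[0, 1]) < 0.1

    def test_constant_column_warns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.warns(UserWarning, match="distinct"):
            g.generate_contrast_data(X, 0)


class TestForest:
    def test_params_defaults_match_study_setting(self):
        p = gc.ForestParams()
        assert (p.ntree, p.mtry, p.nodesize) == (6000, 6, 3)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            gc.ForestParams(ntree=0)
        with pytest.raises(ValueError):
            gc.ForestParams(nodesize=0)

    def test_mtry_exceeding_features_rejected(self, rng):
        X = rng.normal(size=(30, 4))
        with pytest.raises(ValueError, match="mtry"):
            g.fit_proximity_forest(X, None, gc.ForestParams(ntree=10, mtry=5))

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(60, 5))
        p = gc.ForestParams(ntree=50, mtry=2, seed=11)
        a = g.fit_proximity_forest(X, None, p)
        b = g.fit_proximity_forest(X, None, p)
        assert np.array_equal(a.leaf_ids, b.leaf_ids)
        assert np.array_equal(a.oob, b.oob)
        assert np.array_equal(a.importance, b.importance)

    def test_structure_carrying_features_rank_top_in_importance(self, rng):
        """Cluster structure spanning two features creates the only
        inter-feature dependence, so those features dominate importance."""
        X, _ = two_blob_features(rng, n=300, p=12, n_informative=2, shift=2.0)
        fit = g.fit_proximity_forest(X, None, gc.ForestParams(ntree=300, mtry=3, seed=0))
        top2 = set(np.argsort(fit.importance)[-2:])
        assert top2 == {0, 1}


class TestProximity:
    def test_contract_symmetric_unit_diagonal_unit_range(self, rng):
        X = rng.normal(size=(80, 6))
        fit = g.fit_proximity_forest(X, None, gc.ForestParams(ntree=300, mtry=3, seed=1))
        prox = g.compute_oob_proximity(fit)
        P = prox.values
        assert np.allclose(P, P.T)
        assert np.allclose(np.diag(P), 1.0)
        assert P.min() >= 0.0 and P.max() <= 1.0

    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(40, 5))
        fit = g.fit_proximity_forest(X, None, gc.ForestParams(ntree=80, mtry=2, seed=2))
        prox = g.compute_oob_proximity(fit)
        n = 40
        num = np.zeros((n, n))
        den = np.zeros((n, n))
        for t in range(fit.ntree):
            for i in range(n):
                for j in range(n):
                    if fit.oob[t, i] and fit.oob[t, j]:
                        den[i, j] += 1
                        if fit.leaf_ids[t, i] == fit.leaf_ids[t, j]:
                            num[i, j] += 1
        expected = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(prox.values, expected)
        assert np.array_equal(prox.denominators, den)

    def test_duplicated_rows_are_maximally_proximate(self, rng):
        X = rng.normal(size=(50, 5))
        X[1] = X[0]  # exact duplicate pair
        fit = g.fit_proximity_forest(X, None, gc.ForestParams(ntree=500, mtry=2, seed=3))
        prox = g.compute_oob_proximity(fit)
        assert prox.values[0, 1] >= 0.95

    def test_blob_structure_visible_in_proximity(self, rng):
        X, labels = two_blob_features(rng, n=100, p=10)
        fit = g.fit_proximity_forest(X, None, gc.ForestParams(ntree=400, mtry=3, seed=4))
        P = g.compute_oob_proximity(fit).values
        within = P[np.ix_(labels == 1, labels == 1)].mean()
        between = P[np.ix_(labels == 1, labels == 2)].mean()
        assert within > between

    def test_too_few_trees_raise_on_undefined_pairs(self, rng):
        X = rng.normal(size=(200, 4))
        fit = g.fit_proximity_forest(X, None, gc.ForestParams(ntree=3, mtry=2, seed=5))
        with pytest.raises(RuntimeError, match="jointly OOB"):
            g.compute_oob_proximity(fit)


class TestDissimilarity:
    def test_bounds_and_monotonicity(self):
        P = np.array([[1.0, 0.75, 0.0], [0.75, 1.0, 0.36], [0.0, 0.36, 1.0]])
        D = g.proximity_to_dissimilarity(P)
        assert D[0, 0] == 0.0
        assert D[0, 2] == pytest.approx(1.0)
        assert D[0, 1] == pytest.approx(0.5)
        assert D[0, 1] < D[1, 2] < D[0, 2]  # decreasing in proximity

    def test_plain_transform_flag(self):
        P = np.array([[1.0, 0.75], [0.75, 1.0]])
        D = g.proximity_to_dissimilarity(P, sqrt_transform=False)
        assert D[0, 1] == pytest.approx(0.25)


class TestClassicalMds:
    def test_collinear_points_recover_spacing(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        coords, eigval, _ = g.classical_mds(D, 1)
        x = coords[:, 0]
        assert np.allclose(sorted(np.abs(np.diff(sorted(x)))), [1.0, 1.0])

    def test_coordinates_column_centered(self, rng):
        X = rng.normal(size=(25, 4))
        D = squareform(pdist(X))
        coords, _, _ = g.classical_mds(D, 3)
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-10)

    def test_rank_matches_generating_dimension(self, rng):
        X = rng.normal(size=(30, 3))
        D = squareform(pdist(X))
        _, eigval, neg = g.classical_mds(D, 3)
        assert (eigval > 1e-8 * eigval[0]).sum() <= 3
        assert neg < 1e-8

    def test_agrees_with_pcoa_reference(self, rng):
        skbio = pytest.importorskip("skbio")
        X = rng.normal(size=(20, 5))
        D = squareform(pdist(X))
        coords, _, _ = g.classical_mds(D, 3)
        ref = skbio.stats.ordination.pcoa(D, number_of_dimensions=3).samples.to_numpy()
        for j in range(3):  # eigenvectors defined up to sign
            assert min(np.abs(coords[:, j] - ref[:, j]).max(),
                       np.abs(coords[:, j] + ref[:, j]).max()) < 1e-8

    def test_excess_dimensions_truncated_with_warning(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            coords, _, _ = g.classical_mds(D, 3)
        assert coords.shape[1] == 1


class TestHierarchyCut:
    def test_k_one_and_k_n(self, rng):
        X = rng.normal(size=(8, 2))
        D = squareform(pdist(X))
        assert len(set(g.cut_hierarchy(D, 1))) == 1
        assert len(set(g.cut_hierarchy(D, 8))) == 8

    def test_two_separated_blobs_recovered(self, rng):
        X, labels = two_blob_features(rng, n=60, p=6, n_informative=6, shift=3.0)
        D = squareform(pdist(X))
        cut = g.cut_hierarchy(D, 2)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels, cut) == 1.0

    def test_nonfinite_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            g.cut_hierarchy(D, 2)

    def test_canonical_labels_sorted_by_size_and_equivariant(self, rng):
        labels = np.array([3, 3, 3, 1, 1, 2])
        canon = gc.canonicalize_labels(labels)
        assert list(canon) == [1, 1, 1, 2, 2, 3]
        perm = rng.permutation(6)
        assert np.array_equal(gc.canonicalize_labels(labels[perm]), canon[perm])


class TestValidityIndices:
    def test_dunn_hand_case(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        D = squareform(pdist(X))
        assert g.dunn_index(D, [1, 1, 2, 2]) == pytest.approx(9.0)

    def test_dunn_scale_invariant(self, rng):
        X, labels = random_instance(rng)
        D = squareform(pdist(X))
        assert g.dunn_index(3.7 * D, labels) == pytest.approx(
            g.dunn_index(D, labels))

    def test_dunn_matches_oracle_on_random_instances(self, rng):
        for _ in range(30):
            X, labels = random_instance(rng, n=12)
            D = squareform(pdist(X))
            assert g.dunn_index(D, labels) == pytest.approx(
                dunn_oracle(D, labels), abs=1e-12)

    def test_dunn_degenerate_all_identical_within(self):
        D = np.array([[0, 0, 5, 5], [0, 0, 5, 5],
                      [5, 5, 0, 0], [5, 5, 0, 0]], dtype=float)
        assert g.dunn_index(D, [1, 1, 2, 2]) == np.inf

    def test_ch_hand_case(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert g.calinski_harabasz(X, [1, 1, 2, 2]) == pytest.approx(200.0)

    def test_ch_matches_textbook_and_sklearn_oracles(self, rng):
        from sklearn.metrics import calinski_harabasz_score
        for _ in range(30):
            X, labels = random_instance(rng, n=14)
            ours = g.calinski_harabasz(X, labels)
            assert ours == pytest.approx(ch_oracle(X, labels), rel=1e-10)
            assert ours == pytest.approx(
                calinski_harabasz_score(X, labels), rel=1e-8)

    def test_ch_degenerate_zero_scatter(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert g.calinski_harabasz(X, [1, 1, 2, 2]) == np.inf

    def test_ch_k_bounds(self):
        X = np.zeros((4, 1))
        with pytest.raises(ValueError):
            g.calinski_harabasz(X, [1, 1, 1, 1])


class TestCompositeSelection:
    def test_composite_invariant_to_affine_rescaling(self, rng):
        dunn = rng.uniform(0.1, 2.0, 7)
        ch = rng.uniform(10, 500, 7)
        base = g.composite_scores(dunn, ch)
        assert np.allclose(base, g.composite_scores(5 * dunn + 3, ch),
                           rtol=0, atol=1e-12)
        assert np.allclose(base, g.composite_scores(dunn, 0.01 * ch - 7),
                           rtol=0, atol=1e-12)

    def test_search_range_is_two_to_eight(self, rng):
        X, _ = two_blob_features(rng, n=60, p=6, n_informative=6, shift=3.0)
        D = squareform(pdist(X))
        _, table, _ = g.select_k_composite(D, X.to_numpy())
        assert table["k"].tolist() == [2, 3, 4, 5, 6, 7, 8]

    def test_concordant_maxima_win(self, rng):
        X, labels = two_blob_features(rng, n=80, p=6, n_informative=6, shift=4.0)
        D = squareform(pdist(X))
        chosen, table, labs = g.select_k_composite(D, X.to_numpy())
        assert chosen == 2
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels, labs[2]) == 1.0


class TestEndToEnd:
    def test_permutation_equivariance_of_labels(self, rng):
        # unequal blob sizes make the size-ordered canonical labels unique
        labels = np.repeat([1, 2], [40, 20])
        X = pd.DataFrame(rng.standard_normal((60, 6)),
                         columns=[f"f{i}" for i in range(6)])
        X.loc[labels == 2] += 2.5
        params = gc.ForestParams(ntree=200, mtry=3, seed=6)
        sol = g.cluster_features(X, params, k=2)
        # relabeling rows permutes cluster assignment consistently: cutting
        # the same dissimilarity with permuted rows yields permuted labels
        perm = rng.permutation(len(X))
        D = sol.dissimilarity[np.ix_(perm, perm)]
        relabeled = gc.canonicalize_labels(g.cut_hierarchy(D, 2))
        assert np.array_equal(relabeled, sol.labels[perm])

    def test_solution_contract(self, rng):
        X, _ = two_blob_features(rng, n=60, p=6, n_informative=6, shift=2.5)
        sol = g.cluster_features(X, gc.ForestParams(ntree=200, mtry=3, seed=7))
        assert sol.labels.min() == 1
        sizes = np.bincount(sol.labels)[1:]
        assert (sizes > 0).all()
        assert np.all(np.diff(sizes) <= 0)  # cluster 1 is the largest
        assert len(sol.importance) == X.shape[1]
        assert sol.mds_coordinates.shape == (60, 3)

    def test_stability_gap_positive_for_real_blobs(self, rng):
        X, labels = two_blob_features(rng, n=80, p=8, n_informative=8, shift=2.0)
        fit = g.fit_proximity_forest(X, None, gc.ForestParams(ntree=300, mtry=3, seed=8))
        prox = g.compute_oob_proximity(fit)
        gap = g.stability_gap(prox, labels)
        assert (gap["gap"] > 0).all()
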