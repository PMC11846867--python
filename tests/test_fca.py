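import numpy as np
import pandas as pd
import pytest

from scired.fca import (
    FCATable,
    _otsu,
    benchmark_matching,
    build_fca,
    ensemble_score,
    gini,
    global_gini,
    importance_auc,
    importance_knn_permutation,
    importance_logistic,
    importance_trees,
    otsu_threshold,
    permutation_test,
    scale_importances,
)
from scired.io_model import CovariateTable


@pytest.fixture
def labelled_scores(rng):
    """200 cells x 4 factors; factor 0 tracks the labels, the rest are noise."""
    labels = rng.random(200) < 0.4
    scores = rng.normal(size=(200, 4))
    scores[:, 0] = labels * 3.0 + rng.normal(scale=0.3, size=200)
    return scores, labels


class TestImportanceLogistic:
    def test_informative_factor_dominates(self, labelled_scores):
        scores, labels = labelled_scores
        imp = importance_logistic(scores, labels)
        assert np.argmax(imp) == 0

    def test_null_labels_flat_importances(self, rng):
        # permutation-null: no factor should systematically dominate
        wins = np.zeros(3)
        for _ in range(100):
            scores = rng.normal(size=(60, 3))
            labels = rng.permutation([True] * 30 + [False] * 30)
            wins[np.argmax(importance_logistic(scores, labels))] += 1
        assert wins.max() < 60  # ~33 expected per factor under the null

    def test_duplicated_factor_column_no_crash(self, labelled_scores):
        scores, labels = labelled_scores
        dup = np.column_stack([scores, scores[:, 0]])
        imp = importance_logistic(dup, labels)
        assert np.isfinite(imp).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            importance_logistic(rng.normal(size=(10, 2)), np.ones(10, bool))


class TestImportanceAuc:
    def test_perfect_separation(self):
        scores = np.arange(8.0).reshape(-1, 1)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1], bool)
        assert importance_auc(scores, labels)[0] == 1.0

    def test_hand_ranked_example(self):
        # scores {1,2,3,4}, labels {0,0,1,1}: U = 4, AUC = 4/(2*2) = 1
        auc = importance_auc(np.array([[1.0], [2.0], [3.0], [4.0]]),
                             np.array([0, 0, 1, 1], bool))
        assert auc[0] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hand_computed_u(self, seed):
        # enumerated small instances against a direct pairwise U count
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=12).astype(float)  # ties likely
        labels = rng.permutation([True] * 5 + [False] * 7)
        pos, neg = x[labels], x[~labels]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = u / (len(pos) * len(neg))
        got = importance_auc(x.reshape(-1, 1), labels)[0]
        assert got == pytest.approx(max(expected, 1 - expected), abs=1e-12)

    def test_null_approaches_half(self, rng):
        scores = rng.normal(size=(4000, 1))
        labels = rng.random(4000) < 0.5
        assert importance_auc(scores, labels)[0] == pytest.approx(0.5, abs=0.05)

    def test_constant_factor_gives_half(self):
        scores = np.ones((10, 1))
        labels = np.array([True] * 5 + [False] * 5)
        assert importance_auc(scores, labels)[0] == 0.5

    def test_label_swap_symmetry_prefold(self, rng):
        from scipy.stats import rankdata
        x = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        n1, n0 = labels.sum(), (~labels).sum()
        u1 = rankdata(x)[labels].sum() - n1 * (n1 + 1) / 2
        u0 = rankdata(x)[~labels].sum() - n0 * (n0 + 1) / 2
        assert u1 / (n0 * n1) == pytest.approx(1 - u0 / (n0 * n1), abs=1e-12)


class TestImportanceTrees:
    def test_single_informative_factor(self, labelled_scores):
        scores, labels = labelled_scores
        for model in ("decision_tree", "random_forest", "gradient_boosted_trees"):
            imp = importance_trees(scores, labels, model=model)
            assert imp[0] > 0.8
            assert imp.sum() == pytest.approx(1.0)
            assert (imp >= 0).all()

    def test_seeded_determinism(self, labelled_scores):
        scores, labels = labelled_scores
        a = importance_trees(scores, labels, "random_forest", seed=3)
        b = importance_trees(scores, labels, "random_forest", seed=3)
        np.testing.assert_array_equal(a, b)

    def test_depth1_root_split_matches_gini_oracle(self):
        from sklearn.tree import DecisionTreeClassifier

        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0]).reshape(-1, 1)
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = DecisionTreeClassifier(max_depth=1, random_state=0).fit(x, y)
        # root impurity 0.5, children pure: total decrease = 0.5, all on factor 0
        assert clf.feature_importances_[0] == pytest.approx(1.0)
        assert clf.tree_.impurity[0] == pytest.approx(0.5)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            importance_trees(rng.normal(size=(10, 2)), np.zeros(10, bool))


class TestImportanceKnn:
    def test_noise_factor_near_zero_informative_positive(self, labelled_scores):
        scores, labels = labelled_scores
        imp = importance_knn_permutation(scores, labels, seed=0)
        assert imp[0] > 0.1
        assert abs(imp[1]) < 0.1

    def test_seeded_reproducibility(self, labelled_scores):
        scores, labels = labelled_scores
        np.testing.assert_array_equal(
            importance_knn_permutation(scores, labels, seed=1),
            importance_knn_permutation(scores, labels, seed=1),
        )

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            importance_knn_permutation(
                np.zeros((3, 2)), np.array([True, False, True])
            )


class TestScaling:
    def test_minmax_formula(self):
        out = scale_importances(np.array([[1.0, 2.0, 3.0]]), "minmax")
        np.testing.assert_allclose(out, [[0.0, 0.5, 1.0]])

    def test_rank_formula(self):
        out = scale_importances(np.array([[1.0, 2.0, 3.0]]), "rank")
        np.testing.assert_allclose(out, [[1 / 3, 2 / 3, 1.0]])

    def test_standardize_normalization_identity(self, rng):
        out = scale_importances(rng.random((3, 8)), "standardize")
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-12)

    def test_rank_invariant_to_monotone_transform(self, rng):
        raw = rng.random((1, 6))
        np.testing.assert_allclose(
            scale_importances(raw, "rank"),
            scale_importances(np.exp(5 * raw), "rank"),
        )

    def test_zero_spread_rows(self):
        with pytest.warns(UserWarning):
            out = scale_importances(np.array([[2.0, 2.0, 2.0]]), "standardize")
        np.testing.assert_array_equal(out, [[0.0, 0.0, 0.0]])
        with pytest.warns(UserWarning):
            out = scale_importances(np.array([[2.0, 2.0, 2.0]]), "minmax")
        np.testing.assert_array_equal(out, [[0.5, 0.5, 0.5]])


class TestEnsembleScore:
    def test_mean_of_identical_rows(self, rng):
        row = rng.random(5)
        stacked = np.tile(row, (4, 1))
        np.testing.assert_allclose(ensemble_score(stacked, "arithmetic"), row)
        np.testing.assert_allclose(ensemble_score(stacked, "geometric"), row)

    def test_arithmetic_example(self):
        out = ensemble_score(np.array([[0.0, 1.0], [1.0, 0.0]]), "arithmetic")
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_geometric_example(self):
        out = ensemble_score(np.array([[4.0, 1.0], [1.0, 4.0]]), "geometric")
        np.testing.assert_allclose(out, [2.0, 2.0])

    def test_geometric_rejects_negatives(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ensemble_score(np.array([[-1.0, 1.0]]), "geometric")


class TestBuildFca:
    def _cov(self, values, name="group"):
        return CovariateTable(
            pd.DataFrame({name: values},
                         index=[f"c{i}" for i in range(len(values))]),
            {name: "annotation"},
        )

    def test_planted_one_hot_factor_recovered(self, rng):
        labels = np.array(["A"] * 60 + ["B"] * 40)
        scores = rng.normal(size=(100, 3))
        scores[:, 1] = (labels == "B") * 4 + rng.normal(scale=0.2, size=100)
        fca = build_fca(scores, self._cov(labels), seed=0)
        assert fca.scores.loc["group:B"].idxmax() == "F2"

    def test_identical_covariates_identical_rows(self, rng):
        labels = list(rng.choice(["A", "B"], size=80))
        cov = CovariateTable(
            pd.DataFrame({"g1": labels, "g2": labels},
                         index=[f"c{i}" for i in range(80)]),
            {"g1": "annotation", "g2": "annotation"},
        )
        scores = rng.normal(size=(80, 3))
        fca = build_fca(scores, cov, seed=0)
        np.testing.assert_allclose(
            fca.scores.loc["g1:A"].to_numpy(), fca.scores.loc["g2:A"].to_numpy()
        )

    def test_determinism_across_runs(self, rng):
        labels = rng.choice(["A", "B", "C"], size=90)
        scores = rng.normal(size=(90, 4))
        a = build_fca(scores, self._cov(labels), seed=5)
        b = build_fca(scores, self._cov(labels), seed=5)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_small_level_warns(self, rng):
        labels = np.array(["A"] * 95 + ["B"] * 5)
        scores = rng.normal(size=(100, 3))
        with pytest.warns(UserWarning, match="fewer than 10"):
            build_fca(scores, self._cov(labels), seed=0)

    def test_permuted_labels_reduce_gini(self, planted_run, rng):
        cov = planted_run["cov"]
        model = planted_run["model"]
        real = planted_run["fca"]
        perm_labels = rng.permutation(cov.data["group"].to_numpy())
        cov_perm = CovariateTable(
            pd.DataFrame({"group": perm_labels}, index=cov.data.index),
            {"group": "annotation"},
        )
        permuted = build_fca(model, cov_perm, seed=7, binarize=False)
        assert global_gini(permuted) < global_gini(real)


class TestOtsu:
    def test_two_cluster_pool(self):
        scores = pd.DataFrame([[0.0, 0.0, 0.0, 10.0, 10.0]])
        # exhaustive oracle: every inter-point threshold, maximize w0*w1*(m0-m1)^2
        vals = scores.to_numpy().ravel()
        cands = np.unique(vals)
        best_t, best_v = None, -1
        for t in (cands[:-1] + cands[1:]) / 2:
            lo, hi = vals[vals <= t], vals[vals > t]
            v = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
            if v > best_v:
                best_t, best_v = t, v
        table = FCATable(scores=scores)
        thr, binarized = otsu_threshold(table)
        assert 0.0 < thr < 10.0
        assert binarized.to_numpy().sum() == 2
        # the chosen split must separate the same two classes as the oracle
        assert (vals > thr).sum() == (vals > best_t).sum()

    def test_bimodal_mixture_threshold_between_modes(self, rng):
        vals = np.concatenate([rng.normal(0, 0.5, 300), rng.normal(8, 0.5, 200)])
        thr = _otsu(vals)
        assert 1.5 < thr < 6.5

    def test_constant_scores_no_matches(self):
        table = FCATable(scores=pd.DataFrame([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.warns(UserWarning, match="constant"):
            thr, binarized = otsu_threshold(table)
        assert not binarized.to_numpy().any()


class TestGini:
    def test_identical_values_zero(self):
        assert gini(np.full(7, 3.3)) == 0.0

    def test_printed_formula_two_point(self):
        # (0,1): sum|xi-xj| = 2, n = 2, mean = 0.5 -> 2/(2*4*0.5) = 0.5
        assert gini(np.array([0.0, 1.0])) == pytest.approx(0.5)

    def test_matches_direct_double_sum(self, rng):
        x = rng.random(15)
        n = x.size
        expected = sum(abs(a - b) for a in x for b in x) / (2 * n * n * x.mean())
        assert gini(x) == pytest.approx(expected, rel=1e-12)

    def test_negative_scores_shifted(self):
        # shift invariance is deliberately broken only to reach the domain
        assert gini(np.array([-1.0, 0.0])) == pytest.approx(0.5)

    def test_all_zero_row(self):
        assert gini(np.zeros(4)) == 0.0

    def test_global_is_mean_of_levels(self, rng):
        df = pd.DataFrame(rng.random((4, 6)))
        expected = np.mean([gini(df.iloc[i].to_numpy()) for i in range(4)])
        assert global_gini(df) == pytest.approx(expected)


class TestBenchmarkMatching:
    def _table(self, B):
        df = pd.DataFrame(B)
        t = FCATable(scores=df.astype(float))
        t.threshold = 0.5
        t.binarized = df.astype(bool)
        return t

    def test_permutation_matrix_ideal(self):
        counts = benchmark_matching(self._table(np.eye(4, dtype=bool)))
        assert counts == {"entangled_covariates": 0, "split_factors": 0,
                          "unmatched_levels": 0}

    def test_saturated_matrix(self):
        counts = benchmark_matching(self._table(np.ones((3, 5), dtype=bool)))
        assert counts == {"entangled_covariates": 3, "split_factors": 5,
                          "unmatched_levels": 0}

    def test_hand_enumerated_instance(self):
        B = np.array([
            [1, 1, 0, 0],   # entangled level
            [0, 0, 1, 0],
            [0, 0, 1, 0],   # F3 split across two levels
            [0, 0, 0, 0],   # unmatched level
        ], dtype=bool)
        counts = benchmark_matching(self._table(B))
        assert counts == {"entangled_covariates": 1, "split_factors": 1,
                          "unmatched_levels": 1}

    def test_requires_binarization(self):
        t = FCATable(scores=pd.DataFrame([[0.0, 1.0]]))
        with pytest.raises(ValueError, match="binarize"):
            benchmark_matching(t)


class TestPermutationTest:
    def test_extreme_p_values(self, rng):
        # planted: factor 0 is the label; observed score far above any permutation
        labels = np.array(["A"] * 40 + ["B"] * 40)
        scores = rng.normal(size=(80, 3))
        scores[:, 0] = (labels == "B") * 5 + rng.normal(scale=0.2, size=80)
        cov = CovariateTable(
            pd.DataFrame({"g": labels}, index=[f"c{i}" for i in range(80)]),
            {"g": "annotation"},
        )
        diag = permutation_test(scores, cov, n_perm=20, seed=0,
                                classifiers=("auc_linear", "logistic"))
        assert diag.empirical_p.loc["g:B", "F1"] == 0.0
        assert diag.n_perm == 20

    def test_observed_equal_to_permuted_gives_one(self, rng):
        # constant scores: every permutation reproduces the observed value
        labels = np.array(["A", "B"] * 20)
        scores = np.tile(rng.normal(size=(1, 3)), (40, 1))
        cov = CovariateTable(
            pd.DataFrame({"g": labels}, index=[f"c{i}" for i in range(40)]),
            {"g": "annotation"},
        )
        with pytest.warns(UserWarning):
            diag = permutation_test(scores, cov, n_perm=5, seed=0,
                                    classifiers=("auc_linear",))
        assert (diag.empirical_p.to_numpy() == 1.0).all()

    def test_invalid_n_perm(self, rng, planted_run):
        with pytest.raises(ValueError):
            permutation_test(planted_run["model"], planted_run["cov"], n_perm=0)
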