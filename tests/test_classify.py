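"""Distances, KNN voting, clustering, random forest, ROC and similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ctdnacnv as c
from ctdnacnv.classify import ClassifierReport, report_from_predictions
from ctdnacnv.core import CopyState

N, A1, A2, D1, D2 = (
    CopyState.NEUTRAL,
    CopyState.AMP1,
    CopyState.AMP2PLUS,
    CopyState.DEL1,
    CopyState.DEL2,
)


class TestModHamming:
    def test_worked_example(self):
        a = np.array([N, A1, D1])
        b = np.array([N, A2, A1])
        assert c.mod_hamming(a, b) == pytest.approx(1.5)

    def test_identity(self):
        a = np.array([D2, N, A2])
        assert c.mod_hamming(a, a) == 0.0

    @given(
        st.lists(
            st.tuples(st.integers(-2, 2), st.integers(-2, 2)),
            min_size=1,
            max_size=30,
        )
    )
    def test_symmetry_and_bounds(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        d = c.mod_hamming(a, b)
        assert d == c.mod_hamming(b, a)
        assert 0.0 <= d <= len(pairs)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            c.mod_hamming(np.array([0, 1]), np.array([0]))

    def test_pairwise_matches_scalar(self):
        rng = np.random.default_rng(3)
        X = rng.integers(-2, 3, size=(8, 12))
        D = c.pairwise_mod_hamming(X)
        for i in range(8):
            for j in range(8):
                assert D[i, j] == c.mod_hamming(X[i], X[j])


class TestKnn:
    def test_nearest_identical_neighbour_wins_at_k1(self):
        train = np.array([[A2, A2, N], [D2, D2, D2], [N, N, N]])
        labels = np.array(["T", "U", "V"], dtype=object)
        pred = c.knn_classify(train, labels, np.array([[A2, A2, N]]), k=1)
        assert pred[0] == "T"

    def test_default_k_is_floor_sqrt_n(self):
        rng = np.random.default_rng(4)
        train = rng.integers(-2, 3, size=(150, 10))
        labels = np.array(["a", "b", "c"] * 50, dtype=object)
        test = rng.integers(-2, 3, size=(5, 10))
        default = c.knn_classify(train, labels, test)
        explicit = c.knn_classify(train, labels, test, k=12)  # floor(sqrt 150)
        assert np.array_equal(default, explicit)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            c.knn_classify(np.empty((0, 4)), [], np.zeros((1, 4)))

    def test_leave_one_out_on_separable_cohort(self, small_cohort):
        profiles, y = small_cohort
        pred = c.knn_leave_one_out(profiles.category_matrix(), y.to_numpy())
        assert (pred == y.to_numpy()).mean() >= 0.95


class TestHcluster:
    def test_identical_profiles_merge_first_blocks_separate(self):
        block_a = np.tile([A2, A2, N, N, N, N], (4, 1))
        block_b = np.tile([N, N, N, N, D2, D2], (4, 1))
        X = pd.DataFrame(
            np.vstack([block_a, block_b]),
            index=[f"s{i}" for i in range(8)],
            columns=[f"g{j}" for j in range(6)],
        )
        shuffled = X.iloc[[0, 4, 1, 5, 2, 6, 3, 7]]
        order, reordered = c.hcluster(shuffled)
        leaf_labels = ["a" if s in X.index[:4] else "b" for s in reordered.index]
        # blocks come out contiguous
        assert leaf_labels == sorted(leaf_labels) or leaf_labels == sorted(
            leaf_labels, reverse=True
        )

    def test_empty_subset_rejected(self, small_cohort):
        profiles, _ = small_cohort
        with pytest.raises(ValueError):
            c.hcluster(profiles.categories, segment_subset=[])


class TestRandomForest:
    def test_recovers_separable_cohort(self, small_cohort):
        profiles, y = small_cohort
        _, report = c.rf_model(profiles.categories, y, cv_folds=5, seed=1)
        assert report.accuracy >= 0.95
        assert report.predictions.index.equals(profiles.categories.index)

    def test_class_smaller_than_folds_rejected(self, small_cohort):
        profiles, y = small_cohort
        with pytest.raises(ValueError):
            c.rf_model(profiles.categories, y, cv_folds=20, seed=1)

    def test_importances_tie_break_is_genomic_order(self):
        imp = pd.Series([0.1, 0.1, 0.1, 0.1], index=list("wxyz"))
        report = ClassifierReport(
            classes=["a"],
            predictions=pd.Series(dtype=object),
            confusion=pd.DataFrame([[1]], index=["a"], columns=["a"]),
            tpr=pd.Series([1.0], index=["a"]),
            ppv=pd.Series([1.0], index=["a"]),
            accuracy=1.0,
            importances=imp,
        )
        assert c.important_segments(report, top_q=2) == ["w", "x"]
        with pytest.warns(RuntimeWarning):
            assert c.important_segments(report, top_q=9) == list("wxyz")


class TestRoc:
    def test_perfect_probabilities_hit_the_corner(self):
        labels = pd.Series(["a"] * 5 + ["b"] * 5)
        proba = pd.DataFrame(
            {"a": [1.0] * 5 + [0.0] * 5, "b": [0.0] * 5 + [1.0] * 5}
        )
        curves, optimal = c.roc_and_optimal(proba, labels)
        assert optimal.loc["a", "fpr"] == 0.0
        assert optimal.loc["a", "tpr"] == 1.0
        assert optimal.loc["a", "ppv_at_opt"] == 1.0
        for curve in curves.values():
            assert (curve[["fpr", "tpr"]].iloc[0] == [0.0, 0.0]).all() or (
                curve["fpr"].iloc[0] == 0.0
            )
            assert curve["fpr"].iloc[-1] == 1.0
            assert curve["tpr"].iloc[-1] == 1.0
            assert (curve[["fpr", "tpr"]].diff().iloc[1:] >= 0).all().all()

    def test_label_free_probabilities_give_half_auc(self):
        rng = np.random.default_rng(6)
        n = 2000
        labels = pd.Series(np.where(rng.random(n) < 0.5, "a", "b"))
        pa = rng.random(n)
        proba = pd.DataFrame({"a": pa, "b": 1 - pa})
        curves, _ = c.roc_and_optimal(proba, labels)
        auc = np.trapezoid(curves["a"]["tpr"], curves["a"]["fpr"])
        assert abs(auc - 0.5) < 0.05

    def test_unnormalised_rows_rejected(self):
        labels = pd.Series(["a", "b"])
        proba = pd.DataFrame({"a": [0.9, 0.1], "b": [0.3, 0.9]})
        with pytest.raises(ValueError):
            c.roc_and_optimal(proba, labels)


class TestSimilarity:
    def test_hand_computed_value(self):
        conf = pd.DataFrame(
            [[7, 2, 1], [1, 8, 1], [0, 0, 80]],
            index=["A", "B", "rest"],
            columns=["A", "B", "rest"],
        )
        sim = c.misclass_similarity(conf)
        # alpha = 2/10, beta = 1/10, A_n = B_n = 10, N = 100
        assert sim.S.loc["A", "B"] == pytest.approx(0.06)
        assert sim.S.loc["B", "A"] == pytest.approx(0.06)

    def test_zero_iff_no_cross_errors(self):
        conf = pd.DataFrame(
            [[9, 0, 1], [0, 10, 0], [1, 0, 9]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        sim = c.misclass_similarity(conf)
        assert sim.S.loc["A", "B"] == 0.0
        assert sim.S.loc["A", "C"] > 0.0
        assert np.allclose(sim.S, sim.S.T)
        assert np.all(np.diag(sim.heatmap_matrix()) == 0.0)


class TestPerfMetrics:
    def test_two_class_arithmetic(self):
        conf = pd.DataFrame(
            [[8, 2], [1, 9]], index=["pos", "neg"], columns=["pos", "neg"]
        )
        tpr, ppv, acc = c.perf_metrics(conf)
        assert tpr["pos"] == pytest.approx(0.8)
        assert ppv["pos"] == pytest.approx(8 / 9)
        assert acc == pytest.approx(17 / 20)

    def test_never_predicted_class_has_na_ppv(self):
        conf = pd.DataFrame(
            [[0, 10], [0, 10]], index=["rare", "big"], columns=["rare", "big"]
        )
        _, ppv, _ = c.perf_metrics(conf)
        assert np.isnan(ppv["rare"])

    def test_perfect_confusion(self):
        conf = pd.DataFrame(np.eye(3, dtype=int) * 5, index=list("abc"), columns=list("abc"))
        tpr, ppv, acc = c.perf_metrics(conf)
        assert (tpr == 1.0).all() and (ppv == 1.0).all() and acc == 1.0
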