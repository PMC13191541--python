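"""Splits, classifiers, confusion metrics, majority vote, CIs, ROC/PR, tuning."""

import numpy as np
import pytest

import seedspec as ss


def study_labels(n_acc=32, n_per=100):
    return np.repeat([f"A{i + 1:02d}" for i in range(n_acc)], n_per)


class TestHoldoutSplit:
    def test_study_design_80_20(self):
        labels = study_labels()
        split = ss.stratified_holdout_split(labels, test_fraction=0.2, seed=42)
        assert len(split.train_idx) == 2560 and len(split.test_idx) == 640
        test_labels = labels[split.test_idx]
        _, counts = np.unique(test_labels, return_counts=True)
        assert (counts == 20).all()
        assert len(np.intersect1d(split.train_idx, split.test_idx)) == 0
        assert len(split.train_idx) + len(split.test_idx) == 3200

    def test_validation_fraction_from_train_side_only(self):
        labels = study_labels()
        split = ss.stratified_holdout_split(labels, test_fraction=0.2, seed=42,
                                            val_fraction=0.15)
        assert len(split.val_idx) == 384
        assert len(split.train_idx) == 2176
        assert len(split.test_idx) == 640
        assert len(np.intersect1d(split.val_idx, split.test_idx)) == 0

    def test_zero_fraction_puts_all_rows_in_train(self):
        labels = study_labels(4, 10)
        split = ss.stratified_holdout_split(labels, test_fraction=0.0)
        assert len(split.train_idx) == 40 and len(split.test_idx) == 0

    def test_deterministic_given_seed(self):
        labels = study_labels(4, 10)
        s1 = ss.stratified_holdout_split(labels, seed=3)
        s2 = ss.stratified_holdout_split(labels, seed=3)
        assert np.array_equal(s1.train_idx, s2.train_idx)
        assert np.array_equal(s1.test_idx, s2.test_idx)

    def test_tiny_label_rejected(self):
        with pytest.raises(ValueError):
            ss.stratified_holdout_split(["a", "a", "b", "b", "b", "b", "b"],
                                        test_fraction=0.2)


class TestWithinAccessionKFold:
    def test_study_design_five_fold(self):
        labels = study_labels()
        folds = ss.within_accession_kfold(labels, K=5, seed=42)
        assert len(folds) == 5
        all_test = np.concatenate([f.test_idx for f in folds])
        assert len(all_test) == 3200 and len(np.unique(all_test)) == 3200
        for fold in folds:
            _, counts = np.unique(labels[fold.test_idx], return_counts=True)
            assert (counts == 20).all()  # 20 test seeds per accession per fold
            assert len(np.unique(labels[fold.train_idx])) == 32

    def test_leave_one_out_within_single_label(self):
        folds = ss.within_accession_kfold(["a"] * 4, K=4, seed=0)
        for fold in folds:
            assert len(fold.test_idx) == 1

    def test_k_above_smallest_label_rejected(self):
        with pytest.raises(ValueError):
            ss.within_accession_kfold(["a"] * 3 + ["b"] * 10, K=5)


class TestClassifierRegistry:
    def test_unknown_model_error_lists_available(self):
        with pytest.raises(ValueError, match="linear_svm"):
            ss.fit_baseline_classifier(np.zeros((4, 2)), ["a", "a", "b", "b"],
                                       model="quantum_forest")

    def test_separable_classes_fit_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))])
        y = np.repeat(["a", "b"], 10)
        clf = ss.fit_baseline_classifier(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_conflicting_duplicate_rows_degrade_gracefully(self):
        X = np.zeros((4, 2))
        y = np.array(["a", "b", "a", "b"])
        clf = ss.fit_baseline_classifier(X, y, model="knn", n_neighbors=1)
        assert np.mean(clf.predict(X) == y) < 1.0

    @pytest.mark.parametrize("model", ["knn", "lda", "gaussian_nb"])
    def test_comparator_families_run(self, rng, model):
        X = np.vstack([rng.normal(0, 0.3, (15, 4)), rng.normal(3, 0.3, (15, 4))])
        y = np.repeat(["a", "b"], 15)
        clf = ss.fit_baseline_classifier(X, y, model=model)
        assert np.mean(clf.predict(X) == y) > 0.9


class TestReport:
    def test_perfect_predictions(self):
        y = np.repeat(["a", "b", "c"], 5)
        rep = ss.report_from_predictions(y, y)
        assert rep.accuracy == 1.0 and rep.error_rate == 0.0
        assert rep.total_errors == 0
        assert (rep.per_class["f1"] == 1.0).all()

    def test_reference_benchmark_arithmetic_567_of_640(self):
        # 567 correct of 640 test seeds: accuracy 88.59%, 73 errors
        y_true = study_labels(32, 20)
        y_pred = y_true.copy()
        wrong = np.arange(73)
        y_pred[wrong] = np.roll(y_true, -20)[wrong]
        rep = ss.report_from_predictions(y_true, y_pred)
        assert round(100 * rep.accuracy, 2) == 88.59
        assert rep.total_errors == 73
        assert rep.accuracy + rep.error_rate == pytest.approx(1.0)

    def test_three_class_hand_confusion(self):
        # confusion [[5,1,0],[0,4,2],[1,0,7]] worked by hand
        y_true, y_pred = [], []
        C = [[5, 1, 0], [0, 4, 2], [1, 0, 7]]
        names = ["x", "y", "z"]
        for a in range(3):
            for b in range(3):
                y_true += [names[a]] * C[a][b]
                y_pred += [names[b]] * C[a][b]
        rep = ss.report_from_predictions(y_true, y_pred, class_labels=names)
        assert np.array_equal(rep.confusion, C)
        assert rep.per_class.loc["x", "precision"] == pytest.approx(5 / 6)
        assert rep.per_class.loc["x", "recall"] == pytest.approx(5 / 6)
        assert rep.per_class.loc["y", "precision"] == pytest.approx(4 / 5)
        assert rep.per_class.loc["y", "recall"] == pytest.approx(4 / 6)
        assert rep.per_class.loc["y", "f1"] == pytest.approx(8 / 11)
        assert rep.per_class.loc["z", "precision"] == pytest.approx(7 / 9)
        assert rep.per_class.loc["z", "recall"] == pytest.approx(7 / 8)
        assert rep.per_class.loc["z", "f1"] == pytest.approx(14 / 17)

    def test_balanced_test_weighted_equals_macro_exactly(self, rng):
        y_true = study_labels(8, 10)
        y_pred = rng.choice([f"A{i + 1:02d}" for i in range(8)], size=80)
        rep = ss.report_from_predictions(y_true, y_pred)
        assert rep.f1_weighted == rep.f1_macro
        assert rep.precision_weighted == rep.precision_macro

    def test_f1_is_harmonic_mean_where_defined(self, rng):
        y_true = rng.choice(list("abc"), 60)
        y_pred = rng.choice(list("abc"), 60)
        rep = ss.report_from_predictions(y_true, y_pred)
        for _, row in rep.per_class.iterrows():
            if row["precision"] + row["recall"] > 0:
                hm = 2 * row["precision"] * row["recall"] / (row["precision"] + row["recall"])
                assert row["f1"] == pytest.approx(hm)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            ss.report_from_predictions([], [])


class TestRowNormalized:
    def test_five_of_twenty_is_25_percent(self):
        C = np.zeros((2, 2))
        C[0] = [15, 5]
        C[1] = [0, 20]
        R = ss.row_normalized_confusion(C)
        assert R[0, 1] == 0.25
        assert np.allclose(R.sum(axis=1), 1.0)

    def test_identity_counts_and_empty_rows(self):
        R = ss.row_normalized_confusion(np.eye(3) * 7)
        assert np.array_equal(R, np.eye(3))
        R2 = ss.row_normalized_confusion(np.array([[2, 0], [0, 0]]))
        assert np.all(R2[1] == 0.0)


class TestMajorityVote:
    def test_31_of_32_accessions_correct_is_9688(self):
        y_true = study_labels(32, 20)
        preds = y_true.copy()
        preds[y_true == "A07"] = "A08"  # one accession flips entirely
        acc, outcomes = ss.majority_vote_accuracy(preds, y_true, y_true)
        assert round(100 * acc, 2) == 96.88
        assert outcomes["A07"]["correct"] is False

    def test_all_correct(self):
        y = study_labels(4, 5)
        acc, _ = ss.majority_vote_accuracy(y, y, y)
        assert acc == 1.0

    def test_9_9_2_vote_split_incorrect_under_any_modal_outcome(self):
        y_true = np.array(["A02"] * 20)
        preds = np.array(["A01"] * 9 + ["A03"] * 9 + ["A02"] * 2)
        for policy in ("lexicographic", "incorrect"):
            acc, _ = ss.majority_vote_accuracy(preds, y_true, y_true,
                                               tie_policy=policy)
            assert acc == 0.0

    def test_tie_break_lexicographically_smallest(self):
        y_true = np.array(["A01"] * 4)
        preds = np.array(["A01", "A01", "A03", "A03"])
        acc_lex, _ = ss.majority_vote_accuracy(preds, y_true, y_true)
        acc_strict, _ = ss.majority_vote_accuracy(preds, y_true, y_true,
                                                  tie_policy="incorrect")
        assert acc_lex == 1.0 and acc_strict == 0.0


class TestClusterBootstrap:
    def test_all_correct_flags_give_degenerate_interval(self):
        flags = np.ones(40)
        acc = np.repeat([f"g{i}" for i in range(8)], 5)
        ci = ss.cluster_bootstrap_ci(flags, acc, B=200, seed=0)
        assert ci.low == 1.0 and ci.high == 1.0 and ci.point_estimate == 1.0

    def test_more_clusters_shrink_interval(self, rng):
        widths = []
        for n_clusters in (8, 32):
            per = rng.uniform(0.6, 1.0, n_clusters)
            flags = np.concatenate([rng.random(20) < p for p in per]).astype(float)
            acc = np.repeat([f"g{i}" for i in range(n_clusters)], 20)
            ci = ss.cluster_bootstrap_ci(flags, acc, B=500, seed=1)
            widths.append(ci.high - ci.low)
        assert widths[1] < widths[0]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ss.cluster_bootstrap_ci([1.0, 0.0], ["a", "a"], B=100)
        with pytest.raises(ValueError):
            ss.cluster_bootstrap_ci([1.0, 0.0], ["a", "b"], B=1)

    def test_small_B_warns(self, caplog):
        with caplog.at_level("WARNING"):
            ss.cluster_bootstrap_ci(np.ones(10), np.repeat(["a", "b"], 5), B=50)
        assert "unstable" in caplog.text


class TestExactBinomial:
    def test_perfect_32_of_32_closed_form(self):
        low, high = ss.exact_binomial_ci(32, 32)
        assert high == 1.0
        assert low == pytest.approx(0.025 ** (1 / 32), abs=1e-10)
        assert round(low, 4) == 0.8911

    def test_zero_of_ten_closed_form(self):
        low, high = ss.exact_binomial_ci(0, 10)
        assert low == 0.0
        assert high == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-10)
        assert round(high, 4) == 0.3085

    def test_symmetric_at_half(self):
        low, high = ss.exact_binomial_ci(5, 10)
        assert low == pytest.approx(1 - high, abs=1e-10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ss.exact_binomial_ci(5, 4)


class TestMicroRocPr:
    def test_perfect_ranking_gives_unit_areas(self):
        y = np.array(["a", "b", "a", "b"])
        scores = np.array([[0.9, 0.1], [0.2, 0.8], [0.8, 0.2], [0.1, 0.9]])
        curves = ss.micro_roc_pr(scores, y, ["a", "b"])
        assert curves.auc == pytest.approx(1.0)
        assert curves.ap == pytest.approx(1.0)

    def test_random_scores_near_half_auc(self, rng):
        y = rng.choice(["a", "b", "c"], 3000)
        scores = rng.random((3000, 3))
        curves = ss.micro_roc_pr(scores, y, ["a", "b", "c"])
        assert abs(curves.auc - 0.5) < 0.03

    def test_four_sample_fixture_matches_concordance_oracle(self):
        y = np.array(["a", "b", "b", "a"])
        scores = np.array([[0.7, 0.3], [0.4, 0.6], [0.55, 0.45], [0.2, 0.8]])
        curves = ss.micro_roc_pr(scores, y, ["a", "b"])
        # pooled binary pairs: count concordant + half ties over pos x neg
        onehot = (y[:, None] == np.array(["a", "b"])[None, :]).astype(int).ravel()
        flat = scores.ravel()
        pos = flat[onehot == 1]
        neg = flat[onehot == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert curves.auc == pytest.approx(conc / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ss.micro_roc_pr(np.ones((3, 1)), ["a", "a", "a"], ["a"])


class TestValidationCurve:
    def _train_data(self, rng):
        X = np.vstack([rng.normal(i, 0.4, (40, 3)) for i in range(3)])
        y = np.repeat(["a", "b", "c"], 40)
        return X, y

    def test_singleton_grid(self, rng):
        X, y = self._train_data(rng)
        table = ss.tune_validation_curve("knn", "n_neighbors", [1], X, y, seed=0)
        assert len(table) == 1 and table["best"].iloc[0]

    def test_deterministic_reruns(self, rng):
        X, y = self._train_data(rng)
        t1 = ss.tune_validation_curve("knn", "n_neighbors", [1, 3, 5], X, y, seed=4)
        t2 = ss.tune_validation_curve("knn", "n_neighbors", [1, 3, 5], X, y, seed=4)
        assert t1.equals(t2)
        assert np.isfinite(t1["validation_error"]).all()

    def test_extreme_underfit_scores_worse(self, rng):
        X, y = self._train_data(rng)
        n_fit = len(y) - len(np.unique(y)) * 6  # rows left after the val split
        table = ss.tune_validation_curve("knn", "n_neighbors",
                                         [3, n_fit - 1], X, y, seed=2)
        errs = dict(zip(table["param"], table["validation_error"]))
        assert errs[n_fit - 1] > errs[3]

    def test_empty_grid_rejected(self, rng):
        X, y = self._train_data(rng)
        with pytest.raises(ValueError):
            ss.tune_validation_curve("knn", "n_neighbors", [], X, y)
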