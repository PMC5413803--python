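"""LOOCV contract, confusion metrics, ROC/AUC oracle, group statistics."""

import numpy as np
import pandas as pd
import pytest

import pdtkit as pk
from pdtkit.errors import ContractError, DataError
from tests.conftest import make_gaussian_dataset

SVM = pk.ClassifierSpec("svm")


def counts_to_labels(tp, fn, tn, fp):
    actual = [1] * (tp + fn) + [-1] * (tn + fp)
    predicted = [1] * tp + [-1] * fn + [-1] * tn + [1] * fp
    return actual, predicted


class _MajorityModel:
    """Always predicts the training-fold majority class."""

    def fit(self, data):
        self.label_ = 1 if np.sum(data.y == 1) > np.sum(data.y == -1) else -1
        return self

    def predict(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.label_)

    def decision_score(self, X):
        return np.full(np.atleast_2d(X).shape[0], float(self.label_))


class TestLoocv:
    def test_each_subject_held_out_exactly_once(self, cohort_data):
        folds = pk.loocv(cohort_data, SVM)
        assert len(folds) == cohort_data.n == 26
        assert sorted(f.index for f in folds) == list(range(26))
        assert sorted(f.subject_id for f in folds) == sorted(cohort_data.subject_ids)

    def test_deterministic_replay(self, cohort_data):
        spec = pk.ClassifierSpec("rf", n_trees=30, seed=5)
        a = pk.loocv(cohort_data, spec)
        b = pk.loocv(cohort_data, spec)
        assert [f.score for f in a] == [f.score for f in b]
        assert [f.predicted for f in a] == [f.predicted for f in b]

    def test_majority_classifier_at_most_chance_on_balanced_data(self):
        data = make_gaussian_dataset(5, 5, [0.0], seed=1)
        folds = pk.loocv(data, _MajorityModel)
        acc = np.mean([f.predicted == f.actual for f in folds])
        # removing the held-out subject flips the majority against it
        assert acc <= 0.5

    def test_single_class_fold_rejected(self):
        data = make_gaussian_dataset(1, 9, [5.0], seed=2)
        with pytest.raises(DataError, match="single class"):
            pk.loocv(data, SVM)

    def test_minimum_cohort_size(self):
        data = make_gaussian_dataset(1, 1, [5.0], seed=3)
        with pytest.raises(DataError):
            pk.loocv(data, SVM)

    def test_fixed_subset_restricts_columns(self, cohort_data):
        folds = pk.loocv(cohort_data, SVM, subset=(0, 3))
        assert all(f.subset == (0, 3) for f in folds)


class TestConfusionMetrics:
    def test_worked_example_sixteen_patients_ten_controls(self):
        # 1 of 16 patients and 2 of 10 controls misclassified
        actual, predicted = counts_to_labels(tp=15, fn=1, tn=8, fp=2)
        m = pk.confusion_metrics(actual, predicted)
        assert m["accuracy"] == pytest.approx(23 / 26)
        assert round(m["accuracy"], 3) == 0.885
        assert m["sensitivity"] == pytest.approx(15 / 16)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["f_measure"] == pytest.approx(0.9091, abs=5e-5)

    def test_all_correct(self):
        actual, predicted = counts_to_labels(tp=5, fn=0, tn=5, fp=0)
        m = pk.confusion_metrics(actual, predicted)
        for key in ("sensitivity", "specificity", "accuracy", "f_measure"):
            assert m[key] == 1.0

    def test_zero_denominator_yields_nan_with_warning(self):
        with pytest.warns(UserWarning, match="specificity"):
            m = pk.confusion_metrics([1, 1, 1], [1, 1, -1])
        assert np.isnan(m["specificity"])

    def test_empty_input_rejected(self):
        with pytest.raises(ContractError):
            pk.confusion_metrics([], [])

    def test_accuracy_identity(self):
        rng = np.random.default_rng(0)
        actual = rng.choice([-1, 1], size=40)
        actual[:3], actual[-3:] = 1, -1
        predicted = rng.choice([-1, 1], size=40)
        m = pk.confusion_metrics(actual, predicted)
        n_pos, n_neg = np.sum(actual == 1), np.sum(actual == -1)
        assert m["accuracy"] == pytest.approx(
            (m["sensitivity"] * n_pos + m["specificity"] * n_neg) / 40
        )


def auc_by_pair_counting(actual, scores):
    """Concordant-pair probability with ties counted 1/2 (independent oracle)."""
    actual = np.asarray(actual)
    scores = np.asarray(scores, float)
    pos = scores[actual == 1]
    neg = scores[actual == -1]
    total = concordant = 0.0
    for p in pos:
        for q in neg:
            total += 1
            concordant += 1.0 if p > q else (0.5 if p == q else 0.0)
    return concordant / total


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = pk.roc_auc([1, 1, -1, -1], [0.9, 0.8, 0.2, 0.1])
        assert auc == 1.0

    def test_three_of_four_pairs_concordant(self):
        _, auc = pk.roc_auc([1, 1, -1, -1], [0.9, 0.8, 0.85, 0.1])
        assert auc == pytest.approx(0.75)

    def test_all_scores_tied_gives_half(self):
        _, auc = pk.roc_auc([1, -1, 1, -1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(4)
        actual = np.array([1] * 6 + [-1] * 6)
        points, _ = pk.roc_auc(actual, rng.normal(size=12))
        assert tuple(points[0]) == (0.0, 0.0)
        assert tuple(points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            pk.roc_auc([1, 1], [0.1, 0.2])

    @pytest.mark.parametrize("seed", range(20))
    def test_trapezoid_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        n_pos = int(rng.integers(1, n))
        actual = np.array([1] * n_pos + [-1] * (n - n_pos))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        _, auc = pk.roc_auc(actual, scores)
        assert auc == pytest.approx(auc_by_pair_counting(actual, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        actual = np.array([1] * 8 + [-1] * 7)
        scores = rng.normal(size=15)
        _, base = pk.roc_auc(actual, scores)
        for transform in (lambda s: 3 * s + 1, np.tanh, lambda s: np.exp(s / 2)):
            _, other = pk.roc_auc(actual, transform(scores))
            assert other == pytest.approx(base, abs=1e-12)


class TestCompareGroups:
    def test_identical_distributions_give_t_zero_p_one(self):
        rows = []
        for group in ("patient", "control"):
            for v in (1.0, 2.0, 3.0):
                rows.append({"group": group, **{n: v for n in pk.FEATURE_NAMES}})
        out = pk.compare_groups(pd.DataFrame(rows))
        assert len(out) == 12
        assert np.allclose(out["t"], 0.0)
        assert np.allclose(out["p"], 1.0)

    def test_twelve_rows_on_cohort(self, cohort_frame):
        out = pk.compare_groups(cohort_frame)
        assert list(out["feature"]) == list(pk.FEATURE_NAMES)

    def test_large_separation_is_significant(self):
        rng = np.random.default_rng(7)
        rows = []
        for group, shift in (("patient", 10.0), ("control", 0.0)):
            for _ in range(10):
                rows.append(
                    {"group": group, **{n: shift + rng.normal() for n in pk.FEATURE_NAMES}}
                )
        out = pk.compare_groups(pd.DataFrame(rows))
        assert np.all(out["p"] < 0.001)

    def test_degenerate_variance_warns_nan(self):
        rows = []
        for group in ("patient", "control"):
            for _ in range(3):
                rows.append({"group": group, **{n: 5.0 for n in pk.FEATURE_NAMES}})
        with pytest.warns(UserWarning, match="degenerate"):
            out = pk.compare_groups(pd.DataFrame(rows))
        assert out["t"].isna().all()

    def test_optional_multiplicity_correction(self, cohort_frame):
        out = pk.compare_groups(cohort_frame, correction="holm")
        assert "p_adj" in out.columns
        ok = out["p"].notna()
        assert np.all(out.loc[ok, "p_adj"] >= out.loc[ok, "p"] - 1e-15)


class TestImprovement:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(0.808, 0.885, 9.53), (0.808, 0.923, 14.23), (0.846, 0.923, 9.10), (0.7, 0.7, 0.0)],
    )
    def test_relative_improvement(self, before, after, expected):
        assert pk.relative_improvement(before, after) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ContractError):
            pk.relative_improvement(0.0, 0.5)

    def test_mean_auc_enhancement(self):
        pairs = [(0.806, 0.913), (0.769, 0.956), (0.900, 0.975)]
        assert round(pk.mean_relative_improvement(pairs), 1) == 15.3


class TestSelectionPlacementBias:
    def test_pooled_merit_not_below_nested_on_average(self):
        """Pooled selection sees the held-out subject; its LOOCV accuracy is
        optimistically biased relative to nested selection, on average."""
        pooled_accs, nested_accs = [], []
        for seed in range(50):
            data = make_gaussian_dataset(4, 4, [1.2, 0.0, 0.0], seed=300 + seed)
            rep_p = pk.evaluate_pipeline(data, SVM, fs_mode="pooled")
            rep_n = pk.evaluate_pipeline(data, SVM, fs_mode="nested")
            pooled_accs.append(rep_p.accuracy)
            nested_accs.append(rep_n.accuracy)
        assert np.mean(pooled_accs) >= np.mean(nested_accs)
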