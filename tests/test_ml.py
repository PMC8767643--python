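import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenotyper import ml


def _flower_frame(n=40, seed=0):
    rng = np.random.default_rng(seed)
    k = rng.integers(1, 7, n)
    return pd.DataFrame(
        {
            "plant_id": [f"p{i}" for i in range(n)],
            "das": rng.integers(41, 58, n),
            "flower_pixels": k * 450 + rng.integers(-40, 40, n),
            "est_flowers": k * 4,
            "branch_count": k,
        }
    )


class TestAssembleBranchFeatures:
    def test_three_feature_columns(self):
        table = ml.assemble_branch_features(_flower_frame())
        assert table.feature_columns == ("das", "flower_pixels", "est_flowers")
        assert table.X.shape[1] == 3

    def test_feature_subset_drop(self):
        table = ml.assemble_branch_features(_flower_frame(), drop=["flower_pixels"])
        assert table.feature_columns == ("das", "est_flowers")

    def test_rows_with_missing_values_dropped_and_counted(self):
        frame = _flower_frame(10)
        frame.loc[3, "est_flowers"] = np.nan
        table = ml.assemble_branch_features(frame)
        assert len(table) == 9 and table.n_dropped == 1

    def test_no_labeled_rows_rejected(self):
        frame = _flower_frame(5)
        frame["branch_count"] = np.nan
        with pytest.raises(ValueError):
            ml.assemble_branch_features(frame)


def _stress_frame(n=30, seed=0, das=49):
    rng = np.random.default_rng(seed)
    data = {c: rng.normal(size=n) for c in ml.STRESS_FEATURES if c != "flowering_group"}
    data["flowering_group"] = rng.choice(["early", "intermediate", "late"], n)
    data["das"] = das
    data["stress"] = rng.integers(0, 2, n)
    data["plant_id"] = [f"p{i}" for i in range(n)]
    return pd.DataFrame(data)


class TestAssembleStressFeatures:
    def test_canonical_feature_list_has_twenty_entries(self):
        """The stress feature set enumerates 20 distinct attributes (NIR x2,
        top/side areas and hulls with deltas x8, weights x2, rim area,
        height/width with deltas x4, ExG, flowering group, branch count)."""
        table = ml.assemble_stress_features(_stress_frame())
        assert table.feature_columns == ml.STRESS_FEATURES
        assert table.X.shape[1] == 20

    def test_flowering_group_ordinal_encoding(self):
        frame = _stress_frame(6)
        frame["flowering_group"] = ["late"] * 6
        table = ml.assemble_stress_features(frame)
        assert (table.frame["flowering_group"] == 2).all()

    def test_missing_nir_rows_dropped_and_counted(self):
        frame = _stress_frame(12)
        frame.loc[4, "nir_mean"] = np.nan
        table = ml.assemble_stress_features(frame)
        assert len(table) == 11 and table.n_dropped == 1

    def test_absent_assessment_day_rejected(self):
        with pytest.raises(ValueError, match="no rows"):
            ml.assemble_stress_features(_stress_frame(das=47), das=49)


class TestDownsampleBalance:
    def _table(self, n_pos, n_neg, seed=0):
        frame = _stress_frame(n_pos + n_neg, seed=seed)
        frame["stress"] = [1] * n_pos + [0] * n_neg
        return ml.assemble_stress_features(frame)

    def test_majority_downsampled_to_minority(self):
        table = self._table(166, 133)
        balanced = ml.downsample_balance(table, seed=0)
        assert len(balanced) == 266
        counts = balanced.frame["label"].value_counts()
        assert counts[0] == counts[1] == 133

    def test_minority_rows_all_preserved(self):
        table = self._table(20, 8)
        balanced = ml.downsample_balance(table, seed=3)
        minority_ids = set(table.frame.loc[table.frame["label"] == 0, "plant_id"])
        assert minority_ids <= set(balanced.frame["plant_id"])

    def test_already_balanced_unchanged(self):
        table = self._table(15, 15)
        assert ml.downsample_balance(table, seed=0).frame.equals(table.frame)

    def test_deterministic_given_seed(self):
        table = self._table(40, 25)
        a = ml.downsample_balance(table, seed=7).frame
        b = ml.downsample_balance(table, seed=7).frame
        assert a.equals(b)

    def test_empty_class_rejected(self):
        table = self._table(10, 5)
        table.frame["label"] = 1
        with pytest.raises(ValueError):
            ml.downsample_balance(table, seed=0)


class TestKFoldSplit:
    def test_branch_cohort_fold_sizes(self):
        folds = ml.kfold_split(789, k=5, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert max(sizes) == 158 and 789 - max(sizes) == 631

    def test_stress_cohort_fold_sizes(self):
        folds = ml.kfold_split(266, k=5, seed=0)
        assert max(len(f) for f in folds) == 54
        assert 266 - max(len(f) for f in folds) == 212

    def test_n_equals_k_is_leave_one_out(self):
        folds = ml.kfold_split(5, k=5, seed=0)
        assert all(len(f) == 1 for f in folds)

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            ml.kfold_split(4, k=5, seed=0)

    @pytest.mark.parametrize("n,k", [(17, 5), (100, 3), (266, 5)])
    def test_folds_partition_indices(self, n, k):
        folds = ml.kfold_split(n, k=k, seed=1)
        flat = np.concatenate(folds)
        assert len(flat) == n
        assert set(flat) == set(range(n))
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1


class TestCVRegression:
    def test_exact_linear_labels_perfectly_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 10, size=(100, 3))
        y = X @ [2, 1, 3] + 10  # exactly linear integer response
        frame = pd.DataFrame(X, columns=list(ml.BRANCH_FEATURES))
        frame["branch_count"] = y
        report = ml.cv_regression(ml.assemble_branch_features(frame), "linear", seed=0)
        assert report.mean == pytest.approx(1.0)

    def test_uninformative_features_score_near_chance(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(size=(400, 3)), columns=list(ml.BRANCH_FEATURES))
        frame["branch_count"] = rng.integers(1, 35, 400)  # 34 class labels
        report = ml.cv_regression(ml.assemble_branch_features(frame), "linear", seed=0)
        assert report.mean < 0.15  # chance is ~1/34 for the rounded match

    @pytest.mark.parametrize("algo", ["linear", "huber"])
    def test_five_folds_reported(self, algo):
        report = ml.cv_regression(ml.assemble_branch_features(_flower_frame(60)), algo, seed=0)
        assert len(report.per_fold) == 5
        assert report.sd >= 0

    def test_constant_features_flagged(self):
        frame = _flower_frame(20)
        for c in ml.BRANCH_FEATURES:
            frame[c] = 1.0
        report = ml.cv_regression(ml.assemble_branch_features(frame), "linear", seed=0)
        assert report.flagged


class TestRankAUC:
    def test_perfect_separation(self):
        assert ml.rank_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_concordant_pairs(self):
        # pairs: .9>.8 ok, .9>.2 ok, .3<.8 no, .3>.2 ok -> 3/4
        assert ml.rank_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_ties_count_half(self):
        assert ml.rank_auc([0.5, 0.5], [1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ml.rank_auc([0.1, 0.2], [1, 1])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_sklearn_reference(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], n)  # force ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert ml.rank_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        labels[0], labels[1] = 0, 1
        a = ml.rank_auc(scores, labels)
        assert ml.rank_auc(np.exp(3 * scores) + 7, labels) == pytest.approx(a)

    @pytest.mark.parametrize("seed", [11, 123, 2024])
    def test_label_permutation_null_is_half(self, seed):
        """With labels shuffled independently of scores the AUC stays within
        3 null standard deviations of 0.5 (SD = sqrt((n+1)/(12 n1 n0)))."""
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=500)
        labels = rng.permutation([0, 1] * 250)
        null_sd = np.sqrt(501 / (12 * 250 * 250))
        assert abs(ml.rank_auc(scores, labels) - 0.5) < 3 * null_sd


class TestCVClassification:
    def _table(self, n=120, informative=True, seed=0):
        rng = np.random.default_rng(seed)
        frame = _stress_frame(n, seed=seed)
        y = rng.integers(0, 2, n)
        if informative:
            frame["nir_mean"] = y * 3.0 + rng.normal(scale=0.3, size=n)
        frame["stress"] = y
        return ml.assemble_stress_features(frame)

    @pytest.mark.parametrize("algo", list(ml.CLASSIFIER_NAMES))
    def test_all_algorithms_run_and_separate_signal(self, algo):
        report = ml.cv_classification(self._table(), algo, seed=0)
        assert len(report.per_fold) == 5
        assert report.mean > 0.9
        assert report.aux_metric == "accuracy"

    def test_shuffled_labels_score_near_half(self):
        report = ml.cv_classification(self._table(informative=False, n=200), "lda", seed=0)
        assert abs(report.mean - 0.5) < 0.15

    def test_single_class_fold_skipped_and_flagged(self):
        table = self._table(n=10)
        table.frame["label"] = [1] * 9 + [0]
        report = ml.cv_classification(table, "lda", k=5, seed=0)
        assert report.flagged
        assert len(report.per_fold) < 5


class TestAccuracyFromCounts:
    def test_anthesis_detection_rate(self):
        assert ml.accuracy_from_counts(170, 175) == 97.14

    def test_bounds(self):
        assert ml.accuracy_from_counts(0, 7) == 0.0
        assert ml.accuracy_from_counts(7, 7) == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ml.accuracy_from_counts(0, 0)
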