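import numpy as np
import pytest

from connectrl import (
    FeatureMatrix,
    MlpArchitecture,
    cross_validate,
    roc_auc,
    select_features,
    stratified_folds,
    train_mlp,
)
from connectrl.atlas import DEFAULT_EFFECT_REGIONS
from conftest import pair_count_auc

SMALL_ARCH = MlpArchitecture(epochs=60)


class TestSelectFeatures:
    def test_forced_atlas_region_list(self):
        from connectrl import CohortConfig, generate_cohort, fc_for_cohort
        from connectrl.pipeline import profiles_for_cohort

        cfg = CohortConfig(n_group_a=2, n_group_b=2, n_timepoints=60)
        profiles = profiles_for_cohort(fc_for_cohort(generate_cohort(cfg)))
        fm = select_features(profiles, regions=list(DEFAULT_EFFECT_REGIONS))
        assert fm.feature_names == [
            "Cingulum_Mid_L", "ParaHippocampal_R", "Parietal_Sup_L",
            "Paracentral_Lobule_L", "Paracentral_Lobule_R",
            "Thalamus_L", "Thalamus_R", "Temporal_Inf_R",
        ]
        assert fm.x.shape == (4, 8)

    def test_alpha_one_selects_everything(self, small_profiles, small_table):
        fm = select_features(small_profiles, small_table, alpha=1.0)
        assert fm.x.shape[1] == len(small_profiles[0].region_labels)

    def test_significant_selection_ordered_by_region(self, small_profiles, small_table):
        fm = select_features(small_profiles, small_table, alpha=0.05)
        expected = [r.region_name for r in small_table.rows if r.p_t < 0.05]
        assert fm.feature_names == expected

    def test_no_significant_regions_suggests_override(self, small_profiles, small_table):
        with pytest.raises(ValueError, match="explicit"):
            select_features(small_profiles, small_table, alpha=1e-12)


class TestStratifiedFolds:
    def test_study_sized_fold_balance(self):
        y = np.array([0] * 130 + [1] * 156)
        folds = stratified_folds(y, 10, seed=1)
        sizes = np.bincount(folds, minlength=10)
        assert set(sizes) <= {28, 29}
        for f in range(10):
            assert np.sum((folds == f) & (y == 0)) == 13
            assert np.sum((folds == f) & (y == 1)) in (15, 16)

    def test_leave_one_out_degenerate(self):
        y = np.array([0, 0, 1, 1, 1])
        folds = stratified_folds(y, 5, seed=0)
        assert sorted(folds) == [0, 1, 2, 3, 4]

    def test_determinism(self):
        y = np.array([0, 1] * 20)
        np.testing.assert_array_equal(stratified_folds(y, 4, 9), stratified_folds(y, 4, 9))

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            stratified_folds([0, 1, 0, 1], 1)
        with pytest.raises(ValueError):
            stratified_folds([0, 1], 3)


def blobs(n=100, sep=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, 1.0, size=(n // 2, 2))
    x1 = rng.normal(sep, 1.0, size=(n - n // 2, 2))
    x = np.vstack([x0, x1])
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    return x, y


class TestTrainMlp:
    def test_probabilities_in_unit_interval(self):
        x, y = blobs(seed=1)
        scorer = train_mlp(x, y, SMALL_ARCH, seed=1)
        p = scorer.predict_proba(x)
        assert np.all((p > 0) & (p < 1))

    def test_separable_blobs_learned(self):
        x, y = blobs(seed=2)
        scorer = train_mlp(x, y, SMALL_ARCH, seed=2)
        acc = np.mean((scorer.predict_proba(x) >= 0.5).astype(int) == y)
        assert acc >= 0.95

    def test_deterministic_for_fixed_seed(self):
        x, y = blobs(seed=3)
        p1 = train_mlp(x, y, SMALL_ARCH, seed=7).predict_proba(x)
        p2 = train_mlp(x, y, SMALL_ARCH, seed=7).predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        x = np.zeros((10, 2))
        with pytest.raises(ValueError):
            train_mlp(x, np.zeros(10), SMALL_ARCH)


class TestRocAuc:
    def test_perfect_ranking(self):
        points, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == pytest.approx(1.0)
        np.testing.assert_array_equal(points[0], [0.0, 0.0])
        np.testing.assert_array_equal(points[-1], [1.0, 1.0])

    def test_small_case_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-10)

    def test_chance_level_at_large_n(self):
        rng = np.random.default_rng(12)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, size=2000)
        _, auc = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.random(n), 2)  # rounding forces score ties
        labels = rng.integers(0, 2, size=n)
        if np.unique(labels).size < 2:
            labels[0], labels[1] = 0, 1
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.log(scores + 1.0), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.2, 0.4], [1, 1])


@pytest.fixture(scope="module")
def report():
    x, y = blobs(n=80, sep=3.0, seed=5)
    fm = FeatureMatrix(x=x, feature_names=["f0", "f1"], y=y)
    return cross_validate(fm, arch=SMALL_ARCH, k=5, seed=3)


class TestCrossValidate:
    def test_partition_property(self, report):
        assert report.pooled_confusion.sum() == 80
        assert sum(f.n_test for f in report.fold_results) == 80
        np.testing.assert_array_equal(
            report.pooled_confusion,
            sum(np.array([[f.tn, f.fp], [f.fn, f.tp]]) for f in report.fold_results),
        )

    def test_fold_metric_identities(self, report):
        for f in report.fold_results:
            if f.tp + f.fn:
                assert f.tpr == pytest.approx(f.tp / (f.tp + f.fn))
            if f.fp + f.tn:
                assert f.fpr == pytest.approx(f.fp / (f.fp + f.tn))
            pts = np.asarray(f.roc_points)
            assert np.all(np.diff(pts[:, 0]) >= 0)
            assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_signal_learned(self, report):
        assert report.mean_auc > 0.9
        assert report.overall_accuracy > 0.85

    def test_shuffled_labels_are_chance(self):
        rng = np.random.default_rng(21)
        x, y = blobs(n=80, sep=3.0, seed=6)
        fm = FeatureMatrix(x=x, feature_names=["f0", "f1"], y=rng.permutation(y))
        rep = cross_validate(fm, arch=SMALL_ARCH, k=5, seed=4)
        assert 0.25 <= rep.overall_accuracy <= 0.75
        assert 0.25 <= rep.mean_auc <= 0.75
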