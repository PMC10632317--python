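import numpy as np
import pytest
from scipy import stats

from xmpipe.augment import AugmentParams
from xmpipe.phantom import generate_dataset
from xmpipe.preprocess import PreprocessMethod
from xmpipe.robustness_eval import (
    DegenerateInputError,
    LabeledScores,
    ReferenceClassifier,
    SweepAxis,
    clamp_pvalues,
    delong_ci,
    delong_paired_test,
    fisher_combine,
    perturbation_sweep,
    repeated_splits,
    roc_auc,
    train_reference_classifier,
    undersample_majority,
)


def brute_force_auc(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(LabeledScores([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])) == 1.0

    def test_all_ties(self):
        assert roc_auc(LabeledScores([1, 1, 0, 0], [0.5] * 4)) == 0.5

    def test_hand_case(self):
        assert roc_auc(LabeledScores([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2])) == 0.75

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, dtype=int)
            labels[: max(1, int(rng.integers(1, n)))] = 1
            if labels.all():
                labels[0] = 0
            rng.shuffle(labels)
            scores = np.round(rng.random(n), 2)  # coarse values force ties
            data = LabeledScores(labels, scores)
            assert roc_auc(data) == pytest.approx(brute_force_auc(labels, scores))

    def test_complement_symmetry(self, rng):
        labels = (rng.random(40) < 0.4).astype(int)
        labels[0], labels[1] = 0, 1
        scores = rng.random(40)
        a = roc_auc(LabeledScores(labels, scores))
        b = roc_auc(LabeledScores(labels, -scores))
        assert a + b == pytest.approx(1.0)

    def test_single_class_error(self):
        with pytest.raises(DegenerateInputError):
            roc_auc(LabeledScores([1, 1], [0.5, 0.6]))


class TestDelongCi:
    def test_perfect_separation_zero_var(self):
        res = delong_ci(LabeledScores([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]))
        assert res.auc == 1.0
        assert res.var == 0.0
        assert res.ci95 == (1.0, 1.0)

    def test_auc_consistent_with_roc_auc(self, rng):
        labels = (rng.random(30) < 0.5).astype(int)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        data = LabeledScores(labels, scores)
        assert delong_ci(data).auc == roc_auc(data)

    def test_variance_matches_bootstrap(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(1.0, 1.0, 100)
        neg = rng.normal(0.0, 1.0, 100)
        labels = np.r_[np.ones(100, dtype=int), np.zeros(100, dtype=int)]
        scores = np.r_[pos, neg]
        dl_var = delong_ci(LabeledScores(labels, scores)).var
        boots = []
        for _ in range(2000):
            bp = rng.choice(pos, 100)
            bn = rng.choice(neg, 100)
            boots.append(roc_auc(LabeledScores(labels, np.r_[bp, bn])))
        boot_var = np.var(boots, ddof=1)
        assert abs(dl_var - boot_var) / boot_var < 0.25

    def test_small_class_error(self):
        with pytest.raises(DegenerateInputError):
            delong_ci(LabeledScores([1, 0, 0], [0.9, 0.1, 0.2]))


class TestDelongPairedTest:
    def test_identical_scores_p_one(self, rng):
        labels = np.r_[np.ones(10, dtype=int), np.zeros(10, dtype=int)]
        scores = rng.random(20)
        assert delong_paired_test(scores, scores, labels) == 1.0

    def test_symmetry(self, rng):
        labels = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
        a, b = rng.random(40), rng.random(40)
        assert delong_paired_test(a, b, labels) == pytest.approx(
            delong_paired_test(b, a, labels)
        )

    def test_degenerate_zero_variance_nonzero_diff(self):
        labels = np.array([1, 1, 0, 0])
        a = np.array([0.9, 0.8, 0.1, 0.2])  # AUC 1
        b = np.array([0.1, 0.2, 0.9, 0.8])  # AUC 0
        with pytest.warns(RuntimeWarning):
            assert delong_paired_test(a, b, labels) == 0.0

    def test_type_one_error_sanity(self):
        rng = np.random.default_rng(1)
        labels = np.r_[np.ones(50, dtype=int), np.zeros(50, dtype=int)]
        rejections = 0
        reps = 300
        for _ in range(reps):
            a, b = rng.normal(size=100), rng.normal(size=100)
            if delong_paired_test(a, b, labels) < 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.10


class TestFisherCombine:
    def test_all_ones(self):
        stat, p = fisher_combine([1.0, 1.0, 1.0])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_closed_form_k2(self):
        stat, p = fisher_combine([0.5, 0.5])
        assert stat == pytest.approx(2.7726, abs=1e-4)
        assert p == pytest.approx(0.5966, abs=1e-4)

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_matches_chi2_survival(self, k, rng):
        p_vec = rng.uniform(0.01, 1.0, size=k)
        stat, p = fisher_combine(p_vec)
        assert p == pytest.approx(stats.chi2.sf(stat, df=2 * k), rel=1e-10)

    def test_monotone_in_each_p(self):
        _, p_hi = fisher_combine([0.5, 0.5])
        _, p_lo = fisher_combine([0.5, 0.1])
        assert p_lo < p_hi

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])
        with pytest.raises(ValueError):
            fisher_combine([1.5])

    def test_clamp_pvalues_warns(self):
        with pytest.warns(RuntimeWarning):
            out = clamp_pvalues([0.0, 0.5])
        assert out[0] > 0.0


class TestUndersample:
    def test_counts(self):
        labels = np.r_[np.zeros(70, dtype=int), np.ones(30, dtype=int)]
        idx = undersample_majority(labels, seed=0)
        kept = labels[idx]
        assert (kept == 1).sum() == 30 and (kept == 0).sum() == 30

    def test_balanced_keeps_all(self):
        labels = np.r_[np.zeros(10, dtype=int), np.ones(10, dtype=int)]
        idx = undersample_majority(labels, seed=0)
        assert len(idx) == 20

    def test_seed_determinism(self):
        labels = (np.arange(50) % 3 == 0).astype(int)
        np.testing.assert_array_equal(
            undersample_majority(labels, seed=5), undersample_majority(labels, seed=5)
        )


class TestRepeatedSplits:
    def test_paper_scale_rounding(self):
        splits = repeated_splits(7202, 1, 0.8, seed=0)
        train, val = splits[0]
        assert len(train) == 5762 and len(val) == 1440

    def test_partition_properties(self):
        for train, val in repeated_splits(101, 5, 0.8, seed=3):
            assert len(np.intersect1d(train, val)) == 0
            assert len(np.union1d(train, val)) == 101

    def test_consistent_across_model_settings(self):
        a = repeated_splits(50, 10, 0.8, seed=7)
        b = repeated_splits(50, 10, 0.8, seed=7)
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(va, vb)

    def test_validation(self):
        with pytest.raises(ValueError):
            repeated_splits(10, 0, 0.8, seed=0)
        with pytest.raises(ValueError):
            repeated_splits(10, 1, 1.0, seed=0)


@pytest.fixture(scope="module")
def small_clean_dataset():
    return generate_dataset(60, 0.5, seed=8, size=96, lesion_contrast=0.2)


class TestReferenceClassifier:
    def test_training_auc_on_separable_set(self):
        ds = generate_dataset(200, 0.5, seed=13, size=96, lesion_contrast=0.2)
        clf = train_reference_classifier(
            ds.images, ds.labels, PreprocessMethod.NONE, None, seed=0, feature_grid=16
        )
        scores = clf.score_batch(ds.images)
        assert roc_auc(LabeledScores(ds.labels, scores)) > 0.9

    def test_seed_determinism(self, small_clean_dataset):
        ds = small_clean_dataset
        kw = dict(preprocess=PreprocessMethod.NONE, augment=AugmentParams.conventional(),
                  seed=4, feature_grid=16, n_aug=1)
        a = train_reference_classifier(ds.images, ds.labels, **kw)
        b = train_reference_classifier(ds.images, ds.labels, **kw)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.bias == b.bias

    def test_single_class_error(self, small_clean_dataset):
        ds = small_clean_dataset
        with pytest.raises(DegenerateInputError):
            train_reference_classifier(
                ds.images, np.ones(len(ds.images), dtype=int), seed=0
            )

    def test_too_few_images(self, small_clean_dataset):
        ds = small_clean_dataset
        with pytest.raises(ValueError):
            train_reference_classifier(ds.images[:10], ds.labels[:10], seed=0)

    def test_scores_in_unit_interval(self, small_clean_dataset):
        ds = small_clean_dataset
        clf = train_reference_classifier(
            ds.images, ds.labels, PreprocessMethod.HE, None, seed=0, feature_grid=16
        )
        scores = clf.score_batch(ds.images[:5])
        assert np.all((scores >= 0.0) & (scores <= 1.0))

    def test_json_roundtrip(self, small_clean_dataset, tmp_path):
        ds = small_clean_dataset
        clf = train_reference_classifier(
            ds.images, ds.labels, PreprocessMethod.NONE, None, seed=0, feature_grid=16
        )
        path = tmp_path / "model.json"
        clf.to_json(path)
        back = ReferenceClassifier.from_json(path)
        assert back.score(ds.images[0]) == pytest.approx(clf.score(ds.images[0]))


class TestPerturbationSweep:
    def test_identity_point_and_shapes(self, small_clean_dataset):
        ds = small_clean_dataset

        def statistic(img):
            return float(np.quantile(img.pixels, 0.99) - np.median(img.pixels))

        base_scores = np.array([statistic(im) for im in ds.images])
        base_auc = roc_auc(LabeledScores(ds.labels, base_scores))
        res = perturbation_sweep(
            statistic, ds.images, ds.labels, SweepAxis.GAMMA,
            [0.5, 1.0, 2.0], n_repeats=1, seed=0,
        )
        assert len(res.auc_mean) == len(res.grid) == 3
        assert res.auc_ci.shape == (3, 2)
        idx = int(np.where(res.grid == 1.0)[0][0])
        assert res.auc_mean[idx] == pytest.approx(base_auc)

    def test_noise_axis_degrades(self, small_clean_dataset):
        ds = small_clean_dataset

        def statistic(img):
            return float(np.quantile(img.pixels, 0.99) - np.median(img.pixels))

        res = perturbation_sweep(
            statistic, ds.images, ds.labels, SweepAxis.NOISE,
            [0.0, 0.05, 0.1], n_repeats=5, seed=1,
        )
        ci_width = res.auc_ci[:, 1] - res.auc_ci[:, 0]
        slack = np.maximum(ci_width[:-1], ci_width[1:])
        assert np.all(np.diff(res.auc_mean) <= slack + 1e-9)
        assert res.auc_mean[-1] < res.auc_mean[0]

    def test_grid_must_contain_identity(self, small_clean_dataset):
        ds = small_clean_dataset
        with pytest.raises(ValueError):
            perturbation_sweep(
                lambda img: 0.0, ds.images, ds.labels, SweepAxis.GAMMA,
                [2.0, 3.0], n_repeats=1, seed=0,
            )

    def test_grid_strictly_increasing(self, small_clean_dataset):
        ds = small_clean_dataset
        with pytest.raises(ValueError):
            perturbation_sweep(
                lambda img: 0.0, ds.images, ds.labels, SweepAxis.NOISE,
                [0.0, 0.0, 0.1], n_repeats=1, seed=0,
            )


class TestLabeledScores:
    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            LabeledScores([0, 2], [0.1, 0.2])

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            LabeledScores([0, 1], [np.nan, 0.2])

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            LabeledScores([0, 1, 1], [0.1, 0.2])
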