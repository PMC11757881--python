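"""Confusion metrics, ROC/AUC, SVM evaluation and hyperparameter search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.datasets import make_blobs

import pdcconnect as pc
from pdcconnect.classify import SVMSpec, confusion_metrics, evaluate, tune_svm


def blobs(n=200, sep=8.0, seed=0):
    x, y = make_blobs(n_samples=n, centers=2, cluster_std=1.0,
                      center_box=(-sep / 2, sep / 2), random_state=seed)
    return x, y


GAUSS = SVMSpec(kernel="gaussian", box_constraint=1.0, kernel_scale=2.0)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(50, 50, 0, 0)
        assert (m["accuracy"], m["sensitivity"], m["specificity"], m["precision"]) \
            == (1.0, 1.0, 1.0, 1.0)

    def test_always_wrong(self):
        assert confusion_metrics(0, 0, 10, 10)["accuracy"] == 0.0

    def test_matches_direct_formulas_on_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(1, 500, 4)
            m = confusion_metrics(tp, tn, fp, fn)
            assert m["accuracy"] == (tp + tn) / (tp + tn + fp + fn)
            assert m["sensitivity"] == tp / (tp + fn)
            assert m["specificity"] == tn / (tn + fp)
            assert m["precision"] == tp / (tp + fp)

    def test_zero_denominator_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="sensitivity"):
            m = confusion_metrics(0, 5, 3, 0)
        assert np.isnan(m["sensitivity"])

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)


class TestEvaluate:
    def test_separable_data_perfect_ranking(self):
        """Well-separated classes: AUC = 1 and the operating point is (0, 1)."""
        x, y = blobs(seed=1)
        rep = evaluate(x, y, GAUSS, k=5, repeats=2, seed=0)
        assert rep.auc == pytest.approx(1.0, abs=1e-9)
        assert rep.operating_point == (0.0, 1.0)
        assert rep.accuracy > 0.99

    def test_roc_is_monotone_and_anchored(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((120, 5))
        y = rng.integers(0, 2, 120)
        rep = evaluate(x, y, GAUSS, k=4, repeats=1, seed=0)
        assert rep.fpr[0] == 0.0 and rep.tpr[0] == 0.0
        assert rep.fpr[-1] == 1.0 and rep.tpr[-1] == 1.0
        assert (np.diff(rep.fpr) >= 0).all() and (np.diff(rep.tpr) >= 0).all()

    def test_auc_equals_normalized_mann_whitney(self):
        """Pooled-score AUC equals U / (n+ n-) on the same scores."""
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0.4, 1, (80, 3)), rng.normal(0, 1, (80, 3))])
        y = np.array([1] * 80 + [0] * 80)
        rep = evaluate(x, y, GAUSS, k=4, repeats=1, seed=1)
        # reconstruct pooled held-out scores exactly as evaluate does
        from sklearn.model_selection import StratifiedKFold
        scores = np.empty(len(y), dtype=float)
        cv = StratifiedKFold(n_splits=4, shuffle=True, random_state=1)
        for train, test in cv.split(x, y):
            est = GAUSS.make_estimator()
            est.fit(x[train], y[train])
            scores[test] = est.decision_function(x[test])
        u = stats.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert rep.auc == pytest.approx(u / (80 * 80), abs=1e-12)

    def test_permuted_labels_are_chance_level(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((300, 20))
        y = rng.permutation([0, 1] * 150)
        rep = evaluate(x, y, GAUSS, k=5, repeats=2, seed=2)
        lo, hi = stats.binom.ppf([0.005, 0.995], 300, 0.5) / 300
        assert lo <= rep.accuracy <= hi
        assert 0.45 <= rep.auc <= 0.55

    def test_confusion_counts_account_for_every_row(self):
        x, y = blobs(n=150, sep=2.0, seed=5)
        rep = evaluate(x, y, GAUSS, k=5, repeats=3, seed=0)
        assert rep.tp + rep.tn + rep.fp + rep.fn == 150
        assert rep.accuracy_sd >= 0

    def test_bitwise_reproducible_under_fixed_seed(self):
        x, y = blobs(n=120, sep=3.0, seed=6)
        r1 = evaluate(x, y, GAUSS, k=4, repeats=2, seed=9)
        r2 = evaluate(x, y, GAUSS, k=4, repeats=2, seed=9)
        assert r1.accuracy == r2.accuracy and r1.auc == r2.auc
        assert (r1.tp, r1.tn, r1.fp, r1.fn) == (r2.tp, r2.tn, r2.fp, r2.fn)
        np.testing.assert_array_equal(r1.repeat_accuracies, r2.repeat_accuracies)

    def test_subject_split_needs_enough_subjects(self):
        x, y = blobs(n=40, seed=7)
        groups = np.repeat(np.arange(4), 10)
        with pytest.raises(ValueError, match="subjects per class"):
            evaluate(x, y, GAUSS, groups=groups, split="subject", k=5)

    def test_string_labels_use_positive_class(self):
        x, _ = blobs(n=60, seed=8)
        y = np.array(["AUD-like", "control-like"] * 30)
        rep = evaluate(x, y, GAUSS, k=3, repeats=1, seed=0)
        assert rep.tp + rep.fn == 30  # positives = AUD-like rows


class TestLeakage:
    def test_subject_split_not_easier_than_segment_split(self):
        """With per-subject nuisance variation, grouping folds by subject can
        only make held-out accuracy harder on average (leakage direction)."""
        seg_accs, subj_accs = [], []
        for seed in range(20):
            cfg = pc.gamma_effect_config(n_subjects_per_class=5, duration_s=20,
                                         seed=800 + seed)
            cohort = pc.make_cohort(cfg)
            segs = [s for rec in cohort.recordings for s in pc.segment(rec)]
            feats = pc.extract_features(segs, order=5, band_list=[48])
            x, y, g = feats.band_matrix(48), feats.labels, feats.subjects
            spec = SVMSpec(kernel="gaussian", box_constraint=1.0, kernel_scale=18.0)
            seg_accs.append(evaluate(x, y, spec, k=5, repeats=1, seed=seed).accuracy)
            subj_accs.append(evaluate(x, y, spec, groups=g, split="subject", k=5,
                                      repeats=1, seed=seed).accuracy)
        assert np.mean(seg_accs) >= np.mean(subj_accs)


class TestTuneSVM:
    def test_separable_blobs_reach_high_cv_accuracy(self):
        x, y = blobs(n=120, sep=10.0, seed=10)
        spec = tune_svm(x, y, budget=8, k=4, seed=0)
        rep = evaluate(x, y, spec, k=4, repeats=2, seed=0)
        assert rep.accuracy >= 0.99

    def test_pure_noise_does_not_leak_through_tuning(self):
        """Tuning on noise must not manufacture skill: 5x5 repeated CV accuracy
        of the tuned model stays near chance."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal((200, 10))
        y = np.array([0, 1] * 100)
        spec = tune_svm(x, y, budget=8, k=5, seed=1)
        rep = evaluate(x, y, spec, k=5, repeats=5, seed=1)
        assert 0.40 <= rep.accuracy <= 0.60

    def test_deterministic_given_seed(self):
        x, y = blobs(n=80, sep=3.0, seed=12)
        s1 = tune_svm(x, y, budget=6, k=3, seed=5)
        s2 = tune_svm(x, y, budget=6, k=3, seed=5)
        assert s1 == s2

    def test_needs_minimum_rows(self):
        x, y = blobs(n=12, seed=13)
        with pytest.raises(ValueError, match="10 rows"):
            tune_svm(x, y, budget=5)


class TestPerBandSweep:
    def test_report_count_and_ranking(self, small_gamma_features):
        spec = SVMSpec(kernel="gaussian", box_constraint=1.0, kernel_scale=18.0)
        sweep = pc.per_band_sweep(small_gamma_features,
                                  band_list=[8, 24, 40, 56], spec=spec,
                                  k=3, repeats=1, seed=0)
        assert len(sweep["reports"]) == 4
        assert len(sweep["top5"]) == 4  # fewer bands than five
        assert sweep["ranking"][0] == 56  # the gamma-effect band wins
        assert 0 <= sweep["mean_accuracy"] <= 1

    def test_missing_band_errors(self, small_gamma_features):
        spec = SVMSpec(kernel="gaussian")
        with pytest.raises(ValueError, match="not present"):
            pc.per_band_sweep(small_gamma_features, band_list=[200], spec=spec)


class TestSVMSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            SVMSpec(kernel="sigmoid")
        with pytest.raises(ValueError):
            SVMSpec(box_constraint=-1.0)
        with pytest.raises(ValueError):
            SVMSpec(kernel="polynomial", degree=7)

    def test_estimator_kernels(self):
        assert SVMSpec(kernel="gaussian").make_estimator()["svc"].kernel == "rbf"
        assert SVMSpec(kernel="polynomial").make_estimator()["svc"].kernel == "poly"
        assert SVMSpec(kernel="linear").make_estimator()["svc"].kernel == "linear"


@given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
       st.integers(0, 500))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_confusion_identities_hold_for_any_counts(tp, tn, fp, fn):
    """Accuracy identity and [0,1] bounds hold for arbitrary confusion counts."""
    if tp + tn + fp + fn == 0:
        return
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        m = confusion_metrics(tp, tn, fp, fn)
    assert m["accuracy"] == (tp + tn) / (tp + tn + fp + fn)
    for key in ("accuracy", "sensitivity", "specificity", "precision"):
        assert np.isnan(m[key]) or 0.0 <= m[key] <= 1.0
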