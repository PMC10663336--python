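"""LDA fit, LOOCV, metrics, PCA and the heart-rate confound test."""

import numpy as np
import pytest

from mcgkle import (CmfmRecording, CohortSpec, FeatureMatrix, heart_rate_test,
                    lda_fit, loocv, metrics, pca_project, cohort_segment_sets)


def gaussian_classes(rng, mu0, mu1, n=60, sd=1.0):
    X = np.vstack([rng.normal(mu0, sd, size=(n, len(mu0))),
                   rng.normal(mu1, sd, size=(n, len(mu1)))])
    y = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
    return X, y


class TestLdaFit:
    def test_isotropic_classes_align_weights_with_mean_difference(self):
        rng = np.random.default_rng(0)
        X, y = gaussian_classes(rng, [0, 0], [6, 6], n=400)
        model = lda_fit(X, y, regularization=0.0)
        d = model.mu1 - model.mu0
        cos = model.w @ d / (np.linalg.norm(model.w) * np.linalg.norm(d))
        assert cos > 0.99

    def test_identical_means_give_chance_predictions(self):
        rng = np.random.default_rng(1)
        X, y = gaussian_classes(rng, [0, 0, 0], [0, 0, 0], n=100)
        model = lda_fit(X, y)
        acc = np.mean(model.predict(X) == y)
        assert 0.35 <= acc <= 0.65

    def test_one_dimensional_midpoint_threshold(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        model = lda_fit(X, y, regularization=0.0)
        assert model.threshold / model.w[0] == pytest.approx(5.5)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_singular_covariance_advises_regularization(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 6.0], [3.0, 6.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.raises(np.linalg.LinAlgError, match="regularization"):
            lda_fit(X, y, regularization=0.0)

    def test_predictions_match_sklearn_uniform_priors(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(2)
        X, y = gaussian_classes(rng, [0, 0, 0], [2, 1, -1], n=80)
        ours = lda_fit(X, y, regularization=0.0).predict(X)
        ref = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y).predict(X)
        np.testing.assert_array_equal(ours, ref)


class TestMetrics:
    @pytest.mark.parametrize("counts,expected", [
        ((5, 0, 5, 0), (1.0, 1.0, 1.0)),
        ((0, 5, 0, 5), (0.0, 0.0, 0.0)),
        ((3, 1, 8, 2), (0.75, 0.8, 11 / 14)),
        ((29, 6, 17, 3), (29 / 35, 0.85, 46 / 55)),
    ])
    def test_confusion_arithmetic(self, counts, expected):
        m = metrics(*counts)
        assert (m["sensitivity"], m["specificity"], m["accuracy"]) == \
            pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            metrics(-1, 0, 1, 0)

    def test_zero_denominator_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            m = metrics(0, 0, 3, 1)
        assert np.isnan(m["sensitivity"])
        assert m["accuracy"] == pytest.approx(0.75)


class TestLoocv:
    def test_separable_noiseless_cohort_is_perfect(self):
        # no noise, no pathology heterogeneity: two coherent, well-separated
        # topology clusters
        spec = CohortSpec(n_healthy=5, n_path=5, n_beats=4, beat_noise_sd=0.0,
                          effect_size=1.0, healthy_jitter=0.01,
                          pathology_scatter=0.0, seed=8)
        _, sets = cohort_segment_sets(spec)
        report = loocv({"STT": sets["STT"]})
        assert (report.sensitivity, report.specificity, report.accuracy) == \
            (1.0, 1.0, 1.0)

    def test_deterministic_given_inputs(self, small_cohort):
        sets = small_cohort["segments"]
        a = loocv({"STT": sets["STT"]})
        b = loocv({"STT": sets["STT"]})
        np.testing.assert_array_equal(a.y_pred, b.y_pred)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_metrics_equal_recount_of_fold_predictions(self, small_cohort):
        r = loocv({"STT": small_cohort["segments"]["STT"]})
        tp = int(np.sum((r.y_true == 1) & (r.y_pred == 1)))
        tn = int(np.sum((r.y_true == 0) & (r.y_pred == 0)))
        assert r.tp == tp and r.tn == tn
        assert r.accuracy == pytest.approx((tp + tn) / len(r.y_true))

    def test_permuted_labels_score_at_chance(self):
        # destroy the group structure by reassigning group labels; accuracy
        # must fall within the binomial chance band
        from dataclasses import replace
        spec = CohortSpec(n_healthy=11, n_path=11, n_beats=6, effect_size=1.05,
                          seed=31)
        _, sets = cohort_segment_sets(spec)
        rng = np.random.default_rng(0)
        accs = []
        for rep in range(10):
            perm = rng.permutation(22)
            groups = np.array([s.group for s in sets["STT"]])[perm]
            permuted = [replace(s, group=g)
                        for s, g in zip(sets["STT"], groups)]
            accs.append(loocv({"STT": permuted}).accuracy)
        assert 0.3 <= np.mean(accs) <= 0.7

    def test_single_class_training_fold_rejected(self):
        spec = CohortSpec(n_healthy=5, n_path=1, n_beats=4, seed=3)
        _, sets = cohort_segment_sets(spec)
        with pytest.raises(ValueError, match="single-class"):
            loocv({"STT": sets["STT"]})


class TestPca:
    def test_collinear_data_explained_by_first_component(self):
        t = np.linspace(0, 1, 20)
        X = np.outer(t, [1.0, -2.0, 0.5])
        fm = FeatureMatrix(subjects=tuple(map(str, range(20))), X=X,
                           y=np.r_[np.zeros(10, int), np.ones(10, int)],
                           feature_names=("a", "b", "c"))
        out = pca_project(fm, n_components=2)
        assert out["explained_variance_ratio"][0] == pytest.approx(1.0)

    def test_two_points_span_one_component(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0], [1.0, 1.0]])
        fm = FeatureMatrix(subjects=("a", "b", "c"), X=X,
                           y=np.array([0, 1, 0]), feature_names=("f1", "f2"))
        out = pca_project(fm, n_components=2)
        assert out["explained_variance_ratio"][1] == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        fm = FeatureMatrix(subjects=tuple(map(str, range(30))), X=X,
                           y=rng.integers(0, 2, 30),
                           feature_names=tuple("abcd"))
        W = pca_project(fm, n_components=3)["components"]
        for k in range(3):
            assert W[np.argmax(np.abs(W[:, k])), k] > 0

    def test_too_many_components_rejected(self):
        fm = FeatureMatrix(subjects=("a", "b", "c"),
                           X=np.eye(3), y=np.array([0, 1, 0]),
                           feature_names=("x", "y", "z"))
        with pytest.raises(ValueError, match="n_components"):
            pca_project(fm, n_components=4)


def recording_with_hr(subject_id, group, hr_bpm, n_beats=5):
    rr = int(round(60000.0 / hr_bpm))
    r_peaks = 400 + rr * np.arange(n_beats)
    n = int(r_peaks[-1]) + 800
    return CmfmRecording(subject_id=subject_id, group=group,
                         signal=np.zeros((2, n)), fs_hz=1000.0,
                         r_peaks=r_peaks,
                         true_cursors_ms={"qrs_onset": -40, "qrs_end": 50,
                                          "stt_onset": 50, "stt_end": 350})


class TestHeartRateTest:
    def test_identical_rates_maximal_p(self):
        recs = [recording_with_hr(f"H{i}", "healthy", 60 + i) for i in range(3)]
        recs += [recording_with_hr(f"P{i}", "pathology", 60 + i)
                 for i in range(3)]
        assert heart_rate_test(recs)["p_value"] == pytest.approx(1.0)

    def test_separated_rates_exact_p(self):
        recs = [recording_with_hr(f"H{i}", "healthy", hr)
                for i, hr in enumerate([55, 57, 59])]
        recs += [recording_with_hr(f"P{i}", "pathology", hr)
                 for i, hr in enumerate([95, 100, 105])]
        res = heart_rate_test(recs)
        assert res["p_value"] == pytest.approx(0.1)
        assert res["method"] == "exact"

    def test_single_beat_subject_rejected(self):
        rec = CmfmRecording(subject_id="X", group="healthy",
                            signal=np.zeros((2, 2000)), fs_hz=1000.0,
                            r_peaks=np.array([500]),
                            true_cursors_ms={"qrs_onset": -40, "qrs_end": 50,
                                             "stt_onset": 50, "stt_end": 350})
        with pytest.raises(ValueError, match="R peaks"):
            heart_rate_test([rec, recording_with_hr("P", "pathology", 70)])
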