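import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.model_selection import GroupKFold, cross_val_score

from pvfield.classify import (
    GaussianizingScaler,
    NearfieldClassifier,
    ValidationScheme,
    binary_target,
    bootstrap_roc,
    classify_beat,
    fit_normalization,
    forward_select,
    load_model,
    metrics_from_confusion,
    run_validation,
    save_model,
    train_classifier,
)
from pvfield.features import FEATURE_NAMES


def feature_frame(X, y, n_patients=20, seed=0):
    """Wrap a plain (X, y) problem as a feature table with patient metadata."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    frame = pd.DataFrame(X, columns=FEATURE_NAMES[:p])
    for c in FEATURE_NAMES[p:]:
        frame[c] = rng.normal(size=n)
    frame["label"] = np.where(np.asarray(y) == 1, "PV-NF", "atrial-FF")
    frame["patient_id"] = [f"P{i % n_patients:03d}" for i in range(n)]
    frame["vein"] = rng.choice(["LSPV", "LIPV", "RSPV", "RIPV"], size=n)
    frame["phase"] = "during"
    return frame


def two_cloud_frame(n=200, sep=6.0, seed=0, n_patients=20):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2))
    X[y == 1] += sep
    X = np.exp(X)  # strictly positive, log-normal-ish like powers/amplitudes
    return feature_frame(X, y, n_patients=n_patients, seed=seed)


class TestGaussianizingScaler:
    def test_standard_normal_untouched(self):
        X = np.random.default_rng(0).normal(size=(1000, 1))
        sc = GaussianizingScaler().fit(X)
        assert not sc.log_applied_[0]
        assert sc.center_[0] == pytest.approx(0.0, abs=0.1)
        assert sc.scale_[0] == pytest.approx(1.0, abs=0.1)

    def test_lognormal_gets_log_and_loses_skew(self):
        X = np.random.default_rng(1).lognormal(0.0, 1.0, size=(1000, 1))
        sc = GaussianizingScaler().fit(X)
        assert sc.log_applied_[0]
        z = sc.transform(X)
        assert abs(stats.skew(z[:, 0])) < abs(stats.skew(X[:, 0]))
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_constant_feature_errors_with_name(self):
        frame = pd.DataFrame(
            {"p_hf": np.random.default_rng(0).normal(size=50), "v_max": 1.0}
        )
        with pytest.raises(ValueError, match="v_max.*zero variance"):
            fit_normalization(frame, features=["p_hf", "v_max"])

    def test_inverse_round_trip(self):
        X = np.random.default_rng(2).lognormal(size=(200, 3))
        sc = GaussianizingScaler().fit(X)
        np.testing.assert_allclose(sc.inverse_transform(sc.transform(X)), X, rtol=1e-9)


class TestTrainClassifier:
    def test_separated_clouds_svm(self):
        frame = two_cloud_frame(n=200, sep=6.0)
        clf = train_classifier(frame, "svm", ["p_hf", "p_lf"])
        acc = np.mean(clf.predict(frame) == binary_target(frame["label"]))
        assert acc >= 0.99

    def test_single_class_errors(self):
        frame = two_cloud_frame(n=100)
        frame["label"] = "PV-NF"
        with pytest.raises(ValueError, match="single class"):
            train_classifier(frame, "svm", ["p_hf", "p_lf"])

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            train_classifier(two_cloud_frame(), "random_forest")

    def test_knn_k_equals_n_predicts_majority(self):
        frame = two_cloud_frame(n=90, seed=3)
        frame = pd.concat([frame, frame[frame["label"] == "PV-NF"].iloc[:10]])
        clf = train_classifier(
            frame, "knn", ["p_hf", "p_lf"], n_neighbors=len(frame)
        )
        assert (clf.predict(frame) == "nearfield").all()

    @pytest.mark.parametrize("algorithm", ["decision_tree", "lda", "svm", "knn"])
    def test_all_families_fit_and_score(self, algorithm):
        frame = two_cloud_frame(n=120, sep=4.0, seed=4)
        clf = train_classifier(frame, algorithm, ["p_hf", "p_lf"])
        score = clf.decision_function(frame)
        y = binary_target(frame["label"])
        # the score is oriented nearfield-positive for every family
        assert score[y == "nearfield"].mean() > score[y == "farfield"].mean()
        assert np.mean(clf.predict(frame) == y) >= 0.95


class TestForwardSelection:
    def _informative_first_frame(self, n=240, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 4))
        X[:, 1] += 4.0 * y  # only the second candidate is informative
        return feature_frame(np.exp(X), y, seed=seed), FEATURE_NAMES[:4]

    def test_informative_feature_selected_first(self):
        frame, candidates = self._informative_first_frame()
        res = forward_select(frame, "svm", candidate_features=candidates)
        assert res.selected[0] == candidates[1]
        # oracle: exhaustive single-feature grouped CV agrees on the winner
        y = binary_target(frame["label"])
        cv = GroupKFold(n_splits=4)
        groups = frame["patient_id"].to_numpy()
        single = [
            cross_val_score(
                NearfieldClassifier("svm", features=[f]), frame, y,
                groups=groups, cv=cv,
            ).mean()
            for f in candidates
        ]
        assert int(np.argmax(single)) == 1

    def test_pure_noise_stops_early(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 120)
        frame = feature_frame(np.exp(rng.normal(size=(240, 4))), y, seed=1)
        res = forward_select(frame, "lda", candidate_features=FEATURE_NAMES[:4])
        assert len(res.selected) <= 1
        final = res.step_accuracy[-1] if res.step_accuracy else res.baseline_accuracy
        assert final == pytest.approx(50.0, abs=10.0)

    def test_duplicate_feature_selected_once(self):
        frame, candidates = self._informative_first_frame(seed=2)
        frame["p_hf_rel"] = frame[candidates[1]]  # exact duplicate
        res = forward_select(frame, "svm", candidate_features=candidates[:3])
        picked = [f for f in res.selected if frame[f].equals(frame[candidates[1]])]
        assert len(picked) == 1

    def test_needs_two_candidates(self):
        frame, _ = self._informative_first_frame()
        with pytest.raises(ValueError, match="at least 2"):
            forward_select(frame, "svm", candidate_features=["p_hf"])


class TestMetricsAndBootstrap:
    def test_worked_example_confusion(self):
        m = metrics_from_confusion(tp=132, fn=40, fp=18, tn=145)
        assert round(m["sensitivity"]) == 77
        assert round(m["specificity"]) == 89
        assert round(m["accuracy"], 1) == 82.7

    def test_perfect_scores(self):
        labels = np.array(["farfield"] * 50 + ["nearfield"] * 50)
        scores = np.r_[np.zeros(50), np.ones(50)]
        roc = bootstrap_roc(scores, labels, n_boot=200, seed=0)
        assert roc.auc == 1.0
        assert (roc.ci_low, roc.ci_high) == (1.0, 1.0)

    def test_uninformative_scores_auc_half(self):
        rng = np.random.default_rng(0)
        labels = np.array(["farfield", "nearfield"] * 1000)
        scores = rng.normal(size=2000)
        roc = bootstrap_roc(scores, labels, n_boot=200, seed=0)
        assert roc.auc == pytest.approx(0.5, abs=0.03)
        assert roc.ci_low <= roc.auc <= roc.ci_high

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        labels = np.array(["farfield"] * 80 + ["nearfield"] * 80)
        scores = np.r_[rng.normal(size=80), rng.normal(1.0, size=80)]
        a = bootstrap_roc(scores, labels, n_boot=100, seed=2).auc
        b = bootstrap_roc(np.exp(3 * scores), labels, n_boot=100, seed=2).auc
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            bootstrap_roc(np.ones(10), np.array(["nearfield"] * 10), n_boot=100)

    def test_rank_auc_matches_trapezoidal_roc_area(self):
        """The tie-averaged rank AUC equals the area under the empirical
        ROC computed independently by sklearn, including tied scores."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        labels = np.array(["farfield"] * 150 + ["nearfield"] * 150)
        scores = np.round(np.r_[rng.normal(size=150), rng.normal(0.8, size=150)], 1)
        roc = bootstrap_roc(scores, labels, n_boot=100, seed=0)
        assert roc.auc == pytest.approx(
            roc_auc_score(labels == "nearfield", scores), abs=1e-12
        )


class TestRunValidation:
    def test_perfect_predictor(self):
        frame = two_cloud_frame(n=400, sep=8.0, seed=5, n_patients=40)
        rep = run_validation(frame, "svm", ["p_hf", "p_lf"],
                             ValidationScheme(seed=0, n_boot=100))
        assert rep.accuracy == 100.0
        assert rep.roc.auc == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 1000)
        frame = feature_frame(np.exp(rng.normal(size=(2000, 2))), y,
                              n_patients=100, seed=6)
        rep = run_validation(frame, "svm", ["p_hf", "p_lf"],
                             ValidationScheme(seed=1, n_boot=100))
        assert rep.accuracy == pytest.approx(50.0, abs=5.0)

    def test_patient_split_is_structural(self):
        frame = two_cloud_frame(n=200, seed=7)
        rep = run_validation(frame, "lda", ["p_hf", "p_lf"],
                             ValidationScheme(seed=3, n_boot=100))
        hold = set(rep.holdout_patients)
        assert hold and hold < set(frame["patient_id"])
        # confusion identities
        assert rep.tp + rep.fn + rep.fp + rep.tn == rep.n_beats
        m = metrics_from_confusion(rep.tp, rep.fn, rep.fp, rep.tn)
        assert rep.accuracy == pytest.approx(m["accuracy"])
        assert rep.sensitivity == pytest.approx(m["sensitivity"])
        assert rep.specificity == pytest.approx(m["specificity"])
        assert rep.roc.ci_low <= rep.roc.auc <= rep.roc.ci_high

    def test_reproducible_end_to_end(self):
        frame = two_cloud_frame(n=200, sep=3.0, seed=8)
        r1 = run_validation(frame, "svm", ["p_hf", "p_lf"],
                            ValidationScheme(seed=4, n_boot=100))
        r2 = run_validation(frame, "svm", ["p_hf", "p_lf"],
                            ValidationScheme(seed=4, n_boot=100))
        assert r1.to_dict() == r2.to_dict()

    def test_pooled_scope_uses_all_beats(self):
        frame = two_cloud_frame(n=200, sep=3.0, seed=9)
        rep = run_validation(frame, "svm", ["p_hf", "p_lf"],
                             ValidationScheme(seed=0, n_boot=100, scope="pooled"))
        assert rep.n_beats == len(frame)


class TestClassifyBeatAndPersistence:
    def test_one_nn_returns_training_label(self):
        frame = two_cloud_frame(n=60, sep=3.0, seed=10)
        clf = train_classifier(frame, "knn", ["p_hf", "p_lf"], n_neighbors=1)
        row = frame.iloc[17]
        label, _ = classify_beat(clf, {"p_hf": row["p_hf"], "p_lf": row["p_lf"]})
        assert label == binary_target([row["label"]])[0]

    def test_score_deterministic(self):
        frame = two_cloud_frame(n=80, sep=2.0, seed=11)
        clf = train_classifier(frame, "svm", ["p_hf", "v_max"])
        fv = {"p_hf": 1.3, "v_max": 0.4}
        assert classify_beat(clf, fv) == classify_beat(clf, fv)

    def test_missing_feature_errors(self):
        frame = two_cloud_frame(n=80, seed=12)
        clf = train_classifier(frame, "svm", ["p_hf", "v_max"])
        with pytest.raises(ValueError, match="missing"):
            classify_beat(clf, {"p_hf": 1.0})

    @pytest.mark.parametrize("algorithm", ["decision_tree", "lda", "svm", "knn"])
    def test_json_round_trip_preserves_predictions(self, tmp_path, algorithm):
        frame = two_cloud_frame(n=120, sep=2.5, seed=13)
        clf = train_classifier(frame, algorithm, ["p_hf", "p_lf"])
        path = save_model(clf, frame, tmp_path / "model.json")
        back = load_model(path)
        np.testing.assert_array_equal(back.predict(frame), clf.predict(frame))
        np.testing.assert_allclose(
            back.decision_function(frame), clf.decision_function(frame), rtol=1e-12
        )
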