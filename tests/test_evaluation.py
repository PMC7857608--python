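"""Cross-validation plumbing, metric arithmetic, ROC, timelines, t-SNE."""

import numpy as np
import pytest

from rfemotion import (CVPlan, prf_metrics, probability_timeline, roc_ovr,
                       run_cv, tsne_project)
from rfemotion.evaluation import confusion_matrix_counts

LABELS = ["disgust", "joy", "relax", "scary"]


def prf_oracle(cm):
    """Brute-force per-class tally: count TP/FP/FN one cell at a time."""
    k = cm.shape[0]
    out = []
    for c in range(k):
        tp = fp = fn = 0
        for i in range(k):
            for j in range(k):
                if i == c and j == c:
                    tp += cm[i, j]
                elif j == c:
                    fp += cm[i, j]
                elif i == c:
                    fn += cm[i, j]
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        out.append((p, r, f))
    return out


def auc_oracle(scores, positives):
    """P(score+ > score-) with half credit for ties, by exhaustive pairs."""
    pos = scores[positives]
    neg = scores[~positives]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestPrfMetrics:
    def test_perfect_diagonal(self):
        res = prf_metrics(np.diag([15, 15, 15, 15]), LABELS)
        for lab in LABELS:
            assert res["per_class"][lab] == {"precision": 1.0, "recall": 1.0,
                                             "f1": 1.0}
        assert res["accuracy"] == 1.0
        assert res["macro_std"]["f1"] == 0.0

    def test_hand_computed_two_class_block(self):
        cm = np.array([[10, 5, 0, 0], [0, 15, 0, 0],
                       [0, 0, 0, 0], [0, 0, 0, 0]])
        res = prf_metrics(cm, LABELS)
        assert res["per_class"]["disgust"]["precision"] == 1.0
        assert res["per_class"]["disgust"]["recall"] == pytest.approx(2 / 3)
        assert res["per_class"]["disgust"]["f1"] == pytest.approx(0.8)

    def test_permutation_of_classes(self):
        rng = np.random.default_rng(0)
        cm = rng.integers(0, 20, size=(4, 4))
        res = prf_metrics(cm, LABELS)
        perm = [2, 0, 3, 1]
        res_p = prf_metrics(cm[np.ix_(perm, perm)],
                            [LABELS[i] for i in perm])
        assert res_p["macro"] == pytest.approx(res["macro"])
        for i, lab in enumerate(LABELS):
            assert res_p["per_class"][lab] == pytest.approx(
                res["per_class"][lab])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_tally_oracle(self, seed):
        cm = np.random.default_rng(seed).integers(0, 25, size=(4, 4))
        if cm.sum() == 0:
            cm[0, 0] = 1
        res = prf_metrics(cm, LABELS)
        for lab, (p, r, f) in zip(LABELS, prf_oracle(cm)):
            assert res["per_class"][lab]["precision"] == pytest.approx(p)
            assert res["per_class"][lab]["recall"] == pytest.approx(r)
            assert res["per_class"][lab]["f1"] == pytest.approx(f)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            prf_metrics(np.zeros((4, 4)))


class TestRocOvr:
    def test_perfect_separation(self):
        y = np.array(LABELS * 5)
        proba = np.zeros((20, 4))
        for i, lab in enumerate(y):
            proba[i, LABELS.index(lab)] = 1.0
        res = roc_ovr(proba, y, LABELS)
        assert all(a == 1.0 for a in res["per_class_auc"].values())
        assert res["micro_auc"] == 1.0 and res["macro_auc"] == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        y = np.array(LABELS)[rng.integers(0, 4, n)]
        proba = rng.random((n, 4))
        proba /= proba.sum(axis=1, keepdims=True)
        res = roc_ovr(proba, y, LABELS)
        for a in res["per_class_auc"].values():
            assert a == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        y = np.array(LABELS)[rng.integers(0, 4, n)]
        proba = np.round(rng.random((n, 4)), 2)  # rounded to create ties
        res = roc_ovr(proba, y, LABELS)
        for i, lab in enumerate(LABELS):
            positives = y == lab
            if positives.sum() in (0, n):
                continue
            assert res["per_class_auc"][lab] == pytest.approx(
                auc_oracle(proba[:, i], positives), abs=1e-12)

    def test_absent_class_flagged(self):
        y = np.array(["joy", "relax"] * 10)
        proba = np.random.default_rng(0).random((20, 4))
        res = roc_ovr(proba, y, LABELS)
        assert "disgust" in res["undefined_classes"]
        assert np.isnan(res["per_class_auc"]["disgust"])


class _OracleModel:
    """Predicts the true label (leaks the mapping via construction)."""

    def __init__(self, mapping):
        self.mapping = mapping
        self.classes_ = np.array(LABELS)

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        X = np.asarray(X)
        out = np.full((len(X), 4), 0.02)
        for i, x in enumerate(X):
            out[i, int(x[0]) % 4] = 0.94
        return out


class _ConstantModel(_OracleModel):
    def predict_proba(self, X):
        out = np.full((len(np.asarray(X)), 4), 0.1)
        out[:, 2] = 0.7
        return out


class TestRunCv:
    def make_data(self, n_subjects=5):
        idx = np.arange(n_subjects * 4)
        y = np.array(LABELS)[idx % 4]
        groups = np.array([f"S{i // 4}" for i in idx])
        X = (idx % 4).reshape(-1, 1).astype(float)
        return X, y, groups

    def test_loro_has_n_folds(self):
        X, y, groups = self.make_data(15)
        report, details = run_cv(X, y, groups, lambda s: _OracleModel(None),
                                 CVPlan("loro"))
        assert len(details["folds"]) == 60
        assert report.accuracy == 1.0
        assert np.all(report.confusion_matrix == np.diag([15] * 4))

    def test_constant_model_chance_accuracy(self):
        X, y, groups = self.make_data(6)
        report, _ = run_cv(X, y, groups, lambda s: _ConstantModel(None),
                           CVPlan("loso"))
        assert report.accuracy == pytest.approx(0.25)

    def test_loso_no_subject_leakage(self):
        X, y, groups = self.make_data(6)
        _, details = run_cv(X, y, groups, lambda s: _OracleModel(None),
                            CVPlan("loso"))
        for fold in details["folds"]:
            test_subjects = set(groups[fold])
            train_subjects = set(groups) - test_subjects
            assert not test_subjects & train_subjects

    def test_accuracy_equals_weighted_fold_mean(self):
        X, y, groups = self.make_data(5)
        report, details = run_cv(X, y, groups, lambda s: _OracleModel(None),
                                 CVPlan("loso"))
        sizes = np.array([len(f) for f in details["folds"]])
        weighted = np.sum(np.array(details["fold_accuracies"]) * sizes) / sizes.sum()
        assert report.accuracy == pytest.approx(weighted)

    def test_confusion_matrix_sums_to_n(self, network_inputs):
        X_seq, X_img, y, groups = network_inputs
        cm = confusion_matrix_counts(y, y, sorted(set(y)))
        assert cm.sum() == len(y)


class TestProbabilityTimeline:
    def test_constant_model_flat_curves(self, small_dataset):
        model = _ConstantModel(None)
        res = probability_timeline(model, small_dataset[0], window=60.0,
                                   stride=20.0, input_builder=lambda r:
                                   np.zeros((1, 1)))
        np.testing.assert_allclose(res["mean_proba"], [0.1, 0.1, 0.7, 0.1])
        np.testing.assert_allclose(res["proba"].sum(axis=1), 1.0, atol=1e-9)
        assert np.ptp(res["proba"], axis=0).max() < 1e-9

    def test_curves_sum_to_one(self, small_dataset):
        rng = np.random.default_rng(0)

        class Random:
            def predict_proba(self, X):
                p = rng.random((1, 4))
                return p / p.sum()

        res = probability_timeline(Random(), small_dataset[0], window=60.0,
                                   stride=15.0,
                                   input_builder=lambda r: np.zeros((1, 1)))
        np.testing.assert_allclose(res["proba"].sum(axis=1), 1.0, atol=1e-9)

    def test_full_window_single_point(self, small_dataset):
        rec = small_dataset[0]
        res = probability_timeline(_ConstantModel(None), rec,
                                   window=rec.duration, stride=10.0,
                                   input_builder=lambda r: np.zeros((1, 1)))
        assert res["window_proba"].shape == (1, 4)

    def test_bad_stride_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            probability_timeline(_ConstantModel(None), small_dataset[0],
                                 window=60.0, stride=0.0,
                                 input_builder=lambda r: np.zeros((1, 1)))


class TestTsne:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 20))
        a = tsne_project(X, seed=3)
        b = tsne_project(X, seed=3)
        assert a.shape == (40, 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_classes_silhouette(self):
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(1)
        centers = np.array([[6, 0, 0], [0, 6, 0], [0, 0, 6], [-6, -6, -6]])
        y = np.repeat(np.arange(4), 15)
        X = centers[y] + 0.3 * rng.standard_normal((60, 3))
        emb = tsne_project(X, seed=0)
        assert silhouette_score(emb, y) > 0.2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            tsne_project(np.zeros((5, 3)))


def test_export_report_writes_csv_and_png(tmp_path):
    idx = np.arange(20)
    y = np.array(LABELS)[idx % 4]
    groups = np.array([f"S{i // 4}" for i in idx])
    X = (idx % 4).reshape(-1, 1).astype(float)
    from rfemotion import export_report
    report, details = run_cv(X, y, groups, lambda s: _OracleModel(None),
                             CVPlan("loso"))
    export_report(report, details, tmp_path / "out")
    for name in ("report.json", "confusion_matrix.csv", "roc_curves.csv",
                 "confusion_matrix.png", "roc_curves.png"):
        assert (tmp_path / "out" / name).exists()
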