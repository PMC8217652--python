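import numpy as np
import pytest

from fearleak.deception_ml import (
    CLASSIFIER_NAMES,
    FrameDataset,
    classification_metrics,
    crossval_10fold,
    leave_one_person_out,
    smote_oversample,
    train_eval_split,
)
from fearleak.errors import (
    LengthMismatch,
    ParticipantOverlap,
    SingleParticipant,
    TooFewMinority,
)


def make_dataset(
    n_participants=8,
    frames_truth=120,
    frames_lie=20,
    separation=5.0,
    seed=0,
    shuffle_labels=False,
) -> FrameDataset:
    """Synthetic frame dataset: truth ~ N(0, I), lie ~ N(separation, I) in 7-D."""
    rng = np.random.default_rng(seed)
    feats, labels, groups = [], [], []
    for p in range(n_participants):
        X = np.vstack(
            [
                rng.normal(0.0, 1.0, size=(frames_truth, 7)),
                rng.normal(separation, 1.0, size=(frames_lie, 7)),
            ]
        )
        y = np.array(["truth"] * frames_truth + ["lie"] * frames_lie)
        if shuffle_labels:
            rng.shuffle(y)
        feats.append(X)
        labels.append(y)
        groups.append(np.full(len(y), f"P{p:02d}"))
    return FrameDataset(np.vstack(feats), np.concatenate(labels), np.concatenate(groups))


class TestSmote:
    def test_balances_counts(self):
        ds = make_dataset(frames_truth=500 // 4, frames_lie=50 // 4, n_participants=4)
        out = smote_oversample(ds, seed=0)
        labels, counts = np.unique(out.labels, return_counts=True)
        assert counts[0] == counts[1]

    def test_already_balanced_unchanged(self):
        ds = make_dataset(frames_truth=50, frames_lie=50, n_participants=2)
        out = smote_oversample(ds, seed=0)
        assert len(out) == len(ds)
        np.testing.assert_array_equal(out.features, ds.features)

    def test_majority_rows_untouched(self):
        ds = make_dataset(n_participants=4)
        out = smote_oversample(ds, seed=1)
        np.testing.assert_array_equal(out.features[: len(ds)], ds.features)
        np.testing.assert_array_equal(out.labels[: len(ds)], ds.labels)

    def test_synthetic_points_lie_on_knn_segments(self):
        ds = make_dataset(n_participants=3, frames_truth=60, frames_lie=15, seed=2)
        k = 5
        out = smote_oversample(ds, k=k, seed=3)
        synth = out.features[len(ds):]
        assert (out.labels[len(ds):] == "lie").all()
        X_min = ds.features[ds.labels == "lie"]
        # independent neighbor audit: brute-force pairwise distances
        d2 = ((X_min[:, None, :] - X_min[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        knn = np.argsort(d2, axis=1)[:, :k]
        for s in synth:
            on_segment = False
            for i, p in enumerate(X_min):
                for j in knn[i]:
                    q = X_min[j]
                    seg = q - p
                    denom = seg @ seg
                    if denom == 0:
                        continue
                    g = np.clip((s - p) @ seg / denom, 0.0, 1.0)
                    if np.linalg.norm(p + g * seg - s) < 1e-8:
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_too_few_minority(self):
        ds = make_dataset(n_participants=1, frames_truth=50, frames_lie=4)
        with pytest.raises(TooFewMinority):
            smote_oversample(ds, k=5)

    def test_deterministic(self):
        ds = make_dataset(n_participants=4)
        a = smote_oversample(ds, seed=42)
        b = smote_oversample(ds, seed=42)
        np.testing.assert_array_equal(a.features, b.features)


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = np.array(["lie"] * 10 + ["truth"] * 30)
        r = classification_metrics(y, y)
        assert r.accuracy == 100.0
        assert r.kappa == 1.0
        assert r.tp_rate == 1.0
        assert r.fp_rate == 0.0

    def test_constant_majority_prediction(self):
        y_true = np.array(["truth"] * 90 + ["lie"] * 10)
        y_pred = np.array(["truth"] * 100)
        with pytest.warns(UserWarning):
            r = classification_metrics(y_true, y_pred)
        assert r.accuracy == pytest.approx(90.0)
        assert r.kappa == 0.0

    def test_hand_worked_confusion_matrix(self):
        # confusion matrix [[40, 10], [5, 45]] on classes (a, b)
        y_true = np.array(["a"] * 50 + ["b"] * 50)
        y_pred = np.array(["a"] * 40 + ["b"] * 10 + ["a"] * 5 + ["b"] * 45)
        r = classification_metrics(y_true, y_pred)
        assert r.accuracy == pytest.approx(85.0)
        assert r.recall == pytest.approx(0.5 * (40 / 50) + 0.5 * (45 / 50))
        assert r.precision == pytest.approx(0.5 * (40 / 45) + 0.5 * (45 / 55))
        assert r.fp_rate == pytest.approx(0.5 * (5 / 50) + 0.5 * (10 / 50))
        f1_a = 2 * (40 / 45) * (40 / 50) / ((40 / 45) + (40 / 50))
        f1_b = 2 * (45 / 55) * (45 / 50) / ((45 / 55) + (45 / 50))
        assert r.f_measure == pytest.approx(0.5 * f1_a + 0.5 * f1_b)

    def test_weighted_tp_rate_equals_accuracy_fraction(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(["lie", "truth"], 200, p=[0.2, 0.8])
        y_pred = rng.choice(["lie", "truth"], 200, p=[0.3, 0.7])
        r = classification_metrics(y_true, y_pred)
        assert r.tp_rate == pytest.approx(r.accuracy / 100.0)

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatch):
            classification_metrics(np.array(["a"]), np.array(["a", "b"]))

    def test_single_class_test_fold_zero_division_convention(self):
        y_true = np.array(["truth"] * 20)
        y_pred = np.array(["truth"] * 15 + ["lie"] * 5)
        with pytest.warns(UserWarning):
            r = classification_metrics(y_true, y_pred, classes=["lie", "truth"])
        assert r.accuracy == pytest.approx(75.0)
        assert 0.0 <= r.precision <= 1.0


class TestTrainEvalSplit:
    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_separable_classes_high_accuracy(self, name):
        ds = make_dataset(n_participants=8, separation=5.0, seed=1)
        train = [f"P{p:02d}" for p in range(6)]
        r = train_eval_split(ds, train, classifier=name, seed=0)
        assert r.accuracy >= 95.0

    def test_shuffled_labels_near_majority_baseline(self):
        ds = make_dataset(n_participants=8, separation=0.0, seed=2, shuffle_labels=True)
        train = [f"P{p:02d}" for p in range(6)]
        # no SMOTE: the null benchmark compares against the raw class prior
        r = train_eval_split(ds, train, classifier="random_forest", seed=0, use_smote=False)
        test_mask = np.isin(ds.groups, [f"P{p:02d}" for p in range(6, 8)])
        y_test = ds.labels[test_mask]
        baseline = 100.0 * max(np.mean(y_test == "truth"), np.mean(y_test == "lie"))
        assert abs(r.accuracy - baseline) <= 5.0

    def test_explicit_overlap_rejected(self):
        ds = make_dataset(n_participants=4)
        with pytest.raises(ParticipantOverlap):
            train_eval_split(ds, ["P00", "P01"], test_participants=["P01", "P02"])


class TestCrossval:
    @pytest.mark.parametrize("mode", ["paper", "leak_safe"])
    def test_modes_run_and_report(self, mode):
        ds = make_dataset(n_participants=6, frames_truth=60, frames_lie=15, seed=3)
        r = crossval_10fold(ds, classifier="knn", seed=0, mode=mode)
        assert 0.0 <= r.accuracy <= 100.0
        assert -1.0 <= r.kappa <= 1.0

    def test_unknown_mode(self):
        ds = make_dataset(n_participants=2)
        with pytest.raises(ValueError):
            crossval_10fold(ds, mode="nope")


class TestLeaveOnePersonOut:
    def test_fold_count_matches_participants(self):
        ds = make_dataset(n_participants=5, frames_truth=40, frames_lie=12, seed=4)
        res = leave_one_person_out(ds, classifier="knn", seed=0)
        assert len(res.accuracies) == 5
        assert res.mean_accuracy == pytest.approx(np.mean(res.accuracies))

    def test_no_group_leakage(self):
        # audit: training pool of each fold excludes the held-out participant
        ds = make_dataset(n_participants=4, frames_truth=30, frames_lie=10, seed=5)
        participants = np.unique(ds.groups)
        for p in participants:
            train_groups = ds.groups[ds.groups != p]
            assert p not in train_groups

    def test_separated_cohort_high_mean_accuracy(self):
        ds = make_dataset(n_participants=6, separation=5.0, seed=6)
        res = leave_one_person_out(ds, classifier="random_forest", seed=0)
        assert res.mean_accuracy >= 90.0

    def test_single_participant_rejected(self):
        ds = make_dataset(n_participants=1)
        with pytest.raises(SingleParticipant):
            leave_one_person_out(ds)
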