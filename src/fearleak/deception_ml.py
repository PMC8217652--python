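"""Frame-level deception/truth classification.

Covers SMOTE minority oversampling, three classifiers (random forest,
k-nearest-neighbors with k=1, bagged decision trees), a 12-of-16
participant train/test split with frame-level 10-fold CV on the training
pool, leave-one-person-out cross-validation, and an evaluation report with
frequency-weighted per-class metrics plus Cohen's kappa, mirroring the
layout of the WEKA output the numbers are compared against.

Two evaluation modes are provided: ``paper`` applies SMOTE once to the full
training pool before cross-validation (faithful to the original recipe,
but lets resampled frames leak across CV folds); ``leak_safe`` applies
SMOTE inside each training fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.metrics import average_precision_score, cohen_kappa_score, confusion_matrix
from sklearn.neighbors import KNeighborsClassifier

from .errors import LengthMismatch, ParticipantOverlap, SingleParticipant, TooFewMinority

CLASSIFIER_NAMES = ("random_forest", "knn", "bagging")


@dataclass
class FrameDataset:
    """Frame-level feature matrix with labels and participant groups."""

    features: np.ndarray  # (n_frames, n_features)
    labels: np.ndarray  # str array, e.g. {"lie", "truth"}
    groups: np.ndarray  # participant id per frame

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        if not len(self.features) == len(self.labels) == len(self.groups):
            raise LengthMismatch("features, labels and groups must have equal row counts")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, mask: np.ndarray) -> "FrameDataset":
        return FrameDataset(self.features[mask], self.labels[mask], self.groups[mask])


@dataclass(frozen=True)
class ClassifierReport:
    """Accuracy (%) plus frequency-weighted per-class rates and kappa."""

    accuracy: float
    tp_rate: float
    fp_rate: float
    precision: float
    recall: float
    f_measure: float
    prc_area: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "tp_rate": self.tp_rate,
            "fp_rate": self.fp_rate,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "prc_area": self.prc_area,
            "kappa": self.kappa,
        }


def make_classifier(name: str, seed: int | None = None):
    """Instantiate one of the three supported classifiers by name.

    Hyperparameters follow the defaults of the tool the original numbers
    came from: 100 trees for the forest, k=1 neighbors, 10 bagged trees.
    """
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=1)
    if name == "bagging":
        return BaggingClassifier(n_estimators=10, random_state=seed, n_jobs=1)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def smote_oversample(dataset: FrameDataset, k: int = 5, seed: int | None = None) -> FrameDataset:
    """Balance classes by interpolated minority oversampling.

    Each synthetic row is a convex combination of a random minority row and
    one of its ``k`` nearest minority neighbors (Euclidean); majority rows
    are returned untouched.  Synthetic rows inherit the participant group of
    their parent row.
    """
    labels, counts = np.unique(dataset.labels, return_counts=True)
    if len(labels) < 2:
        return dataset
    minority = labels[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return dataset
    min_mask = dataset.labels == minority
    X_min = dataset.features[min_mask]
    g_min = dataset.groups[min_mask]
    if len(X_min) <= k:
        raise TooFewMinority(f"minority class has {len(X_min)} rows; need more than k={k}")
    nn = KNeighborsClassifier(n_neighbors=k + 1).fit(X_min, np.zeros(len(X_min)))
    # neighbor 0 is the point itself
    neigh_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    parents = rng.integers(0, len(X_min), size=n_needed)
    chosen = neigh_idx[parents, rng.integers(0, k, size=n_needed)]
    gaps = rng.random(size=(n_needed, 1))
    synthetic = X_min[parents] + gaps * (X_min[chosen] - X_min[parents])
    return FrameDataset(
        features=np.vstack([dataset.features, synthetic]),
        labels=np.concatenate([dataset.labels, np.full(n_needed, minority, dtype=dataset.labels.dtype)]),
        groups=np.concatenate([dataset.groups, g_min[parents]]),
    )


def classification_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_scores: np.ndarray | None = None,
    classes: Sequence | None = None,
) -> ClassifierReport:
    """Frequency-weighted per-class metrics plus Cohen's kappa.

    ``y_scores`` holds per-class probability columns (ordered as
    ``classes``) and feeds the PRC area (average precision); without it the
    PRC area falls back to the hard predictions.  Per-class metrics that
    are undefined (zero denominator) contribute 0 with a warning.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise LengthMismatch("y_true and y_pred must have equal lengths")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    support = cm.sum(axis=1)
    total = cm.sum()
    weights = support / total

    tp = np.diag(cm).astype(float)
    fn = support - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def _safe(num, den, name):
        out = np.zeros_like(num, dtype=float)
        ok = den > 0
        if not ok.all():
            warnings.warn(f"undefined {name} for class(es) with zero denominator; using 0")
        out[ok] = num[ok] / den[ok]
        return out

    tpr = _safe(tp, tp + fn, "TP rate")
    fpr = _safe(fp, fp + tn, "FP rate")
    prec = _safe(tp, tp + fp, "precision")
    f1_den = prec + tpr
    f1 = np.where(f1_den > 0, 2 * prec * tpr / np.where(f1_den > 0, f1_den, 1), 0.0)

    if y_scores is not None:
        y_scores = np.asarray(y_scores, dtype=float)
        ap = np.array(
            [
                average_precision_score((y_true == c).astype(int), y_scores[:, i])
                if (y_true == c).any()
                else 0.0
                for i, c in enumerate(classes)
            ]
        )
    else:
        ap = np.array(
            [
                average_precision_score((y_true == c).astype(int), (y_pred == c).astype(float))
                if (y_true == c).any()
                else 0.0
                for c in classes
            ]
        )

    accuracy = float(tp.sum() / total)
    kappa = cohen_kappa_score(y_true, y_pred, labels=list(classes)) if len(classes) > 1 else 1.0
    if np.isnan(kappa):  # constant predictor & constant truth
        kappa = 0.0
    return ClassifierReport(
        accuracy=accuracy * 100.0,
        tp_rate=float(np.sum(weights * tpr)),
        fp_rate=float(np.sum(weights * fpr)),
        precision=float(np.sum(weights * prec)),
        recall=float(np.sum(weights * tpr)),
        f_measure=float(np.sum(weights * f1)),
        prc_area=float(np.sum(weights * ap)),
        kappa=float(kappa),
    )


def _fit_predict(clf, train: FrameDataset, test: FrameDataset):
    clf.fit(train.features, train.labels)
    pred = clf.predict(test.features)
    if hasattr(clf, "predict_proba"):
        scores = clf.predict_proba(test.features)
        classes = clf.classes_
    else:
        scores, classes = None, np.unique(train.labels)
    return pred, scores, classes


def train_eval_split(
    dataset: FrameDataset,
    train_participants: Sequence,
    classifier: str = "random_forest",
    seed: int | None = None,
    use_smote: bool = True,
    smote_k: int = 5,
    test_participants: Sequence | None = None,
) -> ClassifierReport:
    """Fit on the given participants' frames, evaluate on the rest.

    ``test_participants`` defaults to every participant not in the training
    set; passing an explicit set that overlaps the training set raises
    :class:`ParticipantOverlap`.  SMOTE (when enabled) is applied to the
    training pool only; test frames are never resampled.
    """
    train_participants = np.asarray(list(train_participants))
    all_participants = np.unique(dataset.groups)
    if test_participants is None:
        test_participants = np.setdiff1d(all_participants, train_participants)
    else:
        test_participants = np.asarray(list(test_participants))
        if len(np.intersect1d(train_participants, test_participants)) > 0:
            raise ParticipantOverlap("train and test participants overlap")
    if len(test_participants) == 0:
        raise ValueError("no participants left for testing")
    train = dataset.subset(np.isin(dataset.groups, train_participants))
    test = dataset.subset(np.isin(dataset.groups, test_participants))
    if use_smote:
        train = smote_oversample(train, k=smote_k, seed=seed)
    clf = make_classifier(classifier, seed=seed)
    pred, scores, classes = _fit_predict(clf, train, test)
    return classification_metrics(test.labels, pred, scores, classes)


def crossval_10fold(
    dataset: FrameDataset,
    classifier: str = "random_forest",
    seed: int | None = None,
    mode: str = "paper",
    smote_k: int = 5,
    n_folds: int = 10,
) -> ClassifierReport:
    """Frame-level k-fold CV over (optionally pre-resampled) frames.

    ``mode='paper'`` resamples the whole pool once before splitting (the
    original recipe); ``mode='leak_safe'`` resamples inside each training
    fold only and keeps folds participant-disjoint.
    """
    rng = np.random.default_rng(seed)
    if mode == "paper":
        pool = smote_oversample(dataset, k=smote_k, seed=seed)
        fold_of = rng.integers(0, n_folds, size=len(pool))
        unit = np.arange(len(pool))
    elif mode == "leak_safe":
        pool = dataset
        participants = np.unique(pool.groups)
        part_fold = dict(
            zip(participants, rng.permutation(len(participants)) % min(n_folds, len(participants)))
        )
        fold_of = np.array([part_fold[g] for g in pool.groups])
        unit = None
    else:
        raise ValueError("mode must be 'paper' or 'leak_safe'")
    y_true, y_pred = [], []
    scores_all = []
    classes = np.unique(pool.labels)
    for f in np.unique(fold_of):
        test_mask = fold_of == f
        train = pool.subset(~test_mask)
        if mode == "leak_safe":
            train = smote_oversample(train, k=smote_k, seed=seed)
        clf = make_classifier(classifier, seed=seed)
        pred, scores, cls = _fit_predict(clf, train, pool.subset(test_mask))
        y_true.append(pool.labels[test_mask])
        y_pred.append(pred)
        if scores is not None:
            aligned = np.zeros((len(pred), len(classes)))
            for i, c in enumerate(classes):
                j = np.where(cls == c)[0]
                if len(j):
                    aligned[:, i] = scores[:, j[0]]
            scores_all.append(aligned)
    y_true = np.concatenate(y_true)
    y_pred = np.concatenate(y_pred)
    scores_arr = np.vstack(scores_all) if scores_all else None
    return classification_metrics(y_true, y_pred, scores_arr, classes)


@dataclass(frozen=True)
class LoocvResult:
    participants: list
    accuracies: list[float]
    mean_accuracy: float
    reports: list[ClassifierReport] = field(repr=False, default_factory=list)


def leave_one_person_out(
    dataset: FrameDataset,
    classifier: str = "random_forest",
    seed: int | None = None,
    use_smote: bool = True,
    smote_k: int = 5,
) -> LoocvResult:
    """One CV fold per participant; no participant appears in both sides."""
    participants = np.unique(dataset.groups)
    if len(participants) < 2:
        raise SingleParticipant("leave-one-person-out needs at least 2 participants")
    accs, reports = [], []
    for p in participants:
        test_mask = dataset.groups == p
        train = dataset.subset(~test_mask)
        test = dataset.subset(test_mask)
        assert not np.isin(train.groups, [p]).any()
        if use_smote and len(np.unique(train.labels)) > 1:
            train = smote_oversample(train, k=smote_k, seed=seed)
        clf = make_classifier(classifier, seed=seed)
        pred, scores, classes = _fit_predict(clf, train, test)
        report = classification_metrics(test.labels, pred, scores, classes)
        accs.append(report.accuracy)
        reports.append(report)
    return LoocvResult(
        participants=list(participants),
        accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        reports=reports,
    )
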