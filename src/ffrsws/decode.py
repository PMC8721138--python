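"""Stimulus decoding from subtracted FFR waveforms.

A one-against-one linear SVM decodes which token evoked each participant's
subtracted average, under repeated 3-fold cross-validation with folds drawn
at the participant level (all of a participant's observations move
together, so no participant appears in both train and test).  Significance
is calibrated against an empirical null built by shuffling token labels on
every iteration, with p = (a + 1)/(n + 1), where a counts null accuracies
exceeding the median of the true distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .preprocess import AveragedFFR

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "DecodingResult",
    "extract_features",
    "ovo_cv",
    "null_distribution",
    "permutation_p",
    "compare_phases",
]


@dataclass
class FeatureSet:
    """Amplitude-by-time feature matrix with observation metadata."""

    matrix: np.ndarray  # observations x features, µV
    labels: np.ndarray  # token per observation
    participants: np.ndarray  # participant id per observation
    phase: str = "pre"
    group: str = "test"

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels)
        self.participants = np.asarray(self.participants)
        n = self.matrix.shape[0]
        if len(self.labels) != n or len(self.participants) != n:
            raise ValueError("labels/participants length mismatch")

    @property
    def n_observations(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def extract_features(
    averages: list[AveragedFFR],
    window_ms: tuple[float, float] = (0.0, 380.0),
    view: str = "subtracted",
) -> FeatureSet:
    """Slice each subtracted average over [0, 380) ms into a feature row.

    At 5,000 Hz the half-open default window yields exactly 1,900
    amplitude-by-time features per observation.  Participant/phase/group
    metadata are read from the averages (missing participants are numbered).
    """
    if window_ms[1] <= window_ms[0]:
        raise ValueError("empty feature window")
    rows, labels, parts = [], [], []
    phases = {a.phase for a in averages}
    groups = {a.group for a in averages}
    if len(phases) > 1 or len(groups) > 1:
        raise ValueError("mix of phases/groups in one feature set; split first")
    for i, avg in enumerate(averages):
        rows.append(avg.slice_ms(view, window_ms[0], window_ms[1]))
        labels.append(avg.token)
        parts.append(avg.participant if avg.participant is not None else i)
    return FeatureSet(
        matrix=np.asarray(rows),
        labels=np.asarray(labels),
        participants=np.asarray(parts),
        phase=next(iter(phases)) or "pre",
        group=next(iter(groups)) or "test",
    )


@dataclass
class DecodingResult:
    """Cross-validated decoding accuracies and their permutation context."""

    iteration_accuracies: np.ndarray
    confusion: np.ndarray  # per-class rates, rows sum to 1
    classes: np.ndarray
    n_folds: int
    null_accuracies: np.ndarray | None = None
    p_vs_null: float | None = None

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.iteration_accuracies))

    def summary(self) -> str:
        lines = [
            "Decoding result",
            "---------------",
            f"iterations        : {len(self.iteration_accuracies)}",
            f"folds             : {self.n_folds}",
            f"median accuracy   : {self.median_accuracy:.3f}",
            f"mean accuracy     : {float(np.mean(self.iteration_accuracies)):.3f}",
        ]
        if self.p_vs_null is not None:
            lines.append(f"p vs null         : {self.p_vs_null:.4g}")
        lines.append("confusion (rows = true class):")
        for cls, row in zip(self.classes, self.confusion):
            lines.append("  " + f"{cls:>6}: " + "  ".join(f"{v:.3f}" for v in row))
        return "\n".join(lines)


def _participant_folds(participants: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random equal split of participants into folds (round-robin remainder)."""
    uniq = np.unique(participants)
    order = rng.permutation(uniq)
    return [order[k::n_folds] for k in range(n_folds)]


def _ovo_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    classes: np.ndarray,
    C: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pairwise linear SVMs with vote-based prediction.

    Ties among vote winners go to the class whose pairwise classifiers had
    the highest mean training accuracy.
    """
    n_cls = len(classes)
    votes = np.zeros((len(X_test), n_cls))
    train_acc = np.zeros((n_cls, n_cls))
    for i in range(n_cls):
        for j in range(i + 1, n_cls):
            mask = (y_train == classes[i]) | (y_train == classes[j])
            clf = SVC(kernel="linear", C=C)
            clf.fit(X_train[mask], y_train[mask])
            acc = clf.score(X_train[mask], y_train[mask])
            train_acc[i, j] = train_acc[j, i] = acc
            pred = clf.predict(X_test)
            for k, cls in enumerate(classes):
                votes[np.asarray(pred) == cls, k] += 1
    out = np.empty(len(X_test), dtype=classes.dtype)
    cls_mean_acc = np.array([train_acc[k][train_acc[k] > 0].mean() if (train_acc[k] > 0).any() else 0 for k in range(n_cls)])
    for m in range(len(X_test)):
        top = votes[m].max()
        tied = np.flatnonzero(votes[m] == top)
        if len(tied) == 1:
            out[m] = classes[tied[0]]
        else:
            out[m] = classes[tied[np.argmax(cls_mean_acc[tied])]]
    return out


def ovo_cv(
    features: FeatureSet,
    n_folds: int = 3,
    n_iterations: int = 2500,
    seed: int = 0,
    C: float = 1.0,
    permute_labels: bool = False,
) -> DecodingResult:
    """Repeated participant-level k-fold cross-validation of the OvO SVM.

    Per iteration participants are randomly and equally divided into
    ``n_folds`` folds; each fold is held out once while the others train the
    N(N−1)/2 pairwise classifiers.  The iteration accuracy is the mean of
    the per-fold accuracies.  With ``permute_labels`` the token labels are
    shuffled uniformly at random before each iteration (the null model).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    uniq_participants = np.unique(features.participants)
    if len(uniq_participants) < n_folds:
        raise ValueError(f"need >= {n_folds} participants, got {len(uniq_participants)}")
    rng = np.random.default_rng(seed)
    classes = features.classes
    n_cls = len(classes)
    cls_index = {c: k for k, c in enumerate(classes)}
    accs = np.empty(n_iterations)
    confusion = np.zeros((n_cls, n_cls))
    n_resampled = 0
    for it in range(n_iterations):
        labels = rng.permutation(features.labels) if permute_labels else features.labels
        for _attempt in range(100):
            folds = _participant_folds(features.participants, n_folds, rng)
            ok = True
            for k in range(n_folds):
                train_mask = ~np.isin(features.participants, folds[k])
                if len(np.unique(labels[train_mask])) < n_cls:
                    ok = False
                    break
            if ok:
                break
            n_resampled += 1
        fold_accs = []
        for k in range(n_folds):
            test_mask = np.isin(features.participants, folds[k])
            train_mask = ~test_mask
            pred = _ovo_predict(
                features.matrix[train_mask],
                labels[train_mask],
                features.matrix[test_mask],
                classes,
                C,
                rng,
            )
            truth = labels[test_mask]
            fold_accs.append(float(np.mean(pred == truth)))
            for t, p in zip(truth, pred):
                confusion[cls_index[t], cls_index[p]] += 1
        accs[it] = float(np.mean(fold_accs))
    if n_resampled:
        logger.info("resampled %d fold splits with a missing training class", n_resampled)
    row_sums = confusion.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    return DecodingResult(
        iteration_accuracies=accs,
        confusion=confusion / row_sums,
        classes=classes,
        n_folds=n_folds,
    )


def null_distribution(
    features: FeatureSet, n_iterations: int = 2500, seed: int = 0, n_folds: int = 3, C: float = 1.0
) -> np.ndarray:
    """Accuracy distribution with labels shuffled on every iteration."""
    res = ovo_cv(features, n_folds=n_folds, n_iterations=n_iterations, seed=seed, C=C, permute_labels=True)
    return res.iteration_accuracies


def permutation_p(true_accuracies: np.ndarray, null_accuracies: np.ndarray) -> float:
    """p = (a + 1)/(n + 1): null values strictly above the true median."""
    true_accuracies = np.asarray(true_accuracies, dtype=float)
    null_accuracies = np.asarray(null_accuracies, dtype=float)
    if true_accuracies.size == 0 or null_accuracies.size == 0:
        raise ValueError("empty distribution")
    a = int(np.sum(null_accuracies > np.median(true_accuracies)))
    n = null_accuracies.size
    return (a + 1) / (n + 1)


def compare_phases(dist_pre: np.ndarray, dist_post: np.ndarray) -> float:
    """Is the post distribution shifted above the pre distribution?

    Treats the pre distribution as the null and the post median as the
    reference: p = (a + 1)/(n + 1) with a the count of pre values strictly
    exceeding the post median.  Small p means post accuracy reliably exceeds
    the pre distribution.
    """
    return permutation_p(dist_post, dist_pre)
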