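"""Condition decoding from single-trial activation patterns.

Implements the multivariate pattern analyses of the pipeline: class
balancing by undersampling, PCA dimensionality reduction fitted on training
data only, a linear maximum-margin classifier, leave-one-run-out and
repeated k-fold cross-validation with bootstrap resampling, ROC-AUC and
accuracy scoring, four-class feature decoding from median-split ratings,
and cross-modal transfer where reduction and classifier are fitted on one
modality and scored on another.

Determinism: every stochastic step (resampling, undersampling, fold
shuffling) draws from a generator seeded by the caller, so identical seeds
give identical per-iteration score vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import TrialBetaMatrix

__all__ = [
    "DecodingResult",
    "undersample",
    "auc_score",
    "reduce_train_project_test",
    "fit_reducer_classifier",
    "cv_decode",
    "cross_modal_decode",
    "feature_decode_4class",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecodingResult:
    """Decoding performance: one score per iteration plus their mean."""

    metric: str  # "auc" or "accuracy"
    per_iteration: np.ndarray
    mean: float
    chance: float

    def __post_init__(self) -> None:
        scores = np.asarray(self.per_iteration, dtype=float)
        if np.any((scores < 0) | (scores > 1)):
            raise ValueError("scores must lie in [0, 1]")
        if not np.isclose(self.mean, scores.mean()):
            raise ValueError("mean must equal the average of per_iteration")


def undersample(
    trials: TrialBetaMatrix, seed: int = 0, per_run: bool = False
) -> TrialBetaMatrix:
    """Balance class counts by seeded random deletion from majority classes.

    With ``per_run=True`` (run-based cross-validation schemes) balancing is
    enforced within every run, and a run missing some class is rejected.
    Trial order is preserved; already-balanced input comes back unchanged.
    """
    classes = trials.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to balance")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    groups = np.unique(trials.run) if per_run else [None]
    for g in groups:
        in_group = np.ones(trials.n_trials, bool) if g is None else trials.run == g
        idx_by_class = [np.flatnonzero(in_group & (trials.condition == c)) for c in classes]
        counts = [len(ix) for ix in idx_by_class]
        if min(counts) == 0:
            where = "dataset" if g is None else f"run {g}"
            raise ValueError(
                f"{where} has zero trials of class "
                f"{classes[int(np.argmin(counts))]!r}; cannot balance"
            )
        m = min(counts)
        for ix in idx_by_class:
            keep.append(ix if len(ix) == m else np.sort(rng.choice(ix, size=m, replace=False)))
    return trials.subset(np.sort(np.concatenate(keep)))


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney formulation.

    The probability that a randomly chosen positive trial outscores a
    randomly chosen negative one, with ties counted 1/2 (midranks) —
    insensitive to any monotone rescaling of the classifier output.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _clamp_components(requested: int | None, n_train: int, n_features: int) -> int:
    cap = max(1, min(n_train - 1, n_features))
    if requested is None:
        return cap
    if requested > cap:
        warnings.warn(
            f"n_components={requested} clamped to {cap} "
            f"(n_train={n_train}, n_features={n_features})",
            RuntimeWarning,
            stacklevel=3,
        )
        return cap
    return max(1, requested)


def reduce_train_project_test(
    train_patterns: np.ndarray,
    test_patterns: np.ndarray,
    n_components: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit PCA on training patterns only; project both sets.

    ``n_components`` is clamped to ``min(requested, n_train - 1,
    n_features)`` with a warning; the default takes the cap itself.
    """
    train_patterns = np.asarray(train_patterns, dtype=float)
    test_patterns = np.asarray(test_patterns, dtype=float)
    if train_patterns.shape[1] != test_patterns.shape[1]:
        raise ValueError(
            f"feature-dimension mismatch: train has {train_patterns.shape[1]}, "
            f"test has {test_patterns.shape[1]}"
        )
    k = _clamp_components(n_components, *train_patterns.shape)
    # Clamp further to the actual rank so degenerate (e.g. rank-1) training
    # data cannot produce spurious zero-variance components.
    centered = train_patterns - train_patterns.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < k:
        warnings.warn(
            f"training data has rank {rank} < n_components={k}; clamping",
            RuntimeWarning,
            stacklevel=2,
        )
        k = max(1, rank)
    pca = PCA(n_components=k, svd_solver="full")
    return pca.fit_transform(train_patterns), pca.transform(test_patterns)


def fit_reducer_classifier(
    train_patterns: np.ndarray,
    train_labels: np.ndarray,
    n_components: int | None = None,
) -> tuple[PCA, SVC]:
    """Fit the reduction + linear classifier pipeline on training data only.

    Every fitted parameter (PCA loadings, support-vector weights) is a
    function of the training fold alone; test data never enters here.
    """
    k = _clamp_components(n_components, *np.asarray(train_patterns).shape)
    pca = PCA(n_components=k, svd_solver="full")
    reduced = pca.fit_transform(train_patterns)
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(reduced, train_labels)
    return pca, clf


def _pooled_scores(
    trials: TrialBetaMatrix,
    folds: list[tuple[np.ndarray, np.ndarray]],
    n_components: int | None,
    positive: object,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per fold: (margins, predictions, true binary labels) on the held-out set.

    Folds whose training half contains a single class are skipped (logged);
    an all-skipped scheme is rejected.
    """
    out = []
    for train_idx, test_idx in folds:
        y_train = trials.condition[train_idx]
        if len(np.unique(y_train)) < 2:
            logger.warning("skipping fold: training half contains a single class")
            continue
        pca, clf = fit_reducer_classifier(
            trials.patterns[train_idx], y_train, n_components
        )
        reduced = pca.transform(trials.patterns[test_idx])
        preds = clf.predict(reduced)
        y_true = trials.condition[test_idx]
        binary = positive is not None and len(clf.classes_) == 2
        if binary:
            margins = clf.decision_function(reduced)
            if clf.classes_[1] != positive:  # orient margins toward `positive`
                margins = -margins
        else:
            margins = np.zeros(len(test_idx))
        out.append((margins, preds == positive if binary else preds,
                    y_true == positive if binary else y_true))
    if not out:
        raise ValueError("all folds skipped: no fold had both classes in training")
    return out


def _loro_folds(run: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    return [
        (np.flatnonzero(run != r), np.flatnonzero(run == r)) for r in np.unique(run)
    ]


def _kfold_folds(
    condition: np.ndarray, k: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
    return [(tr, te) for tr, te in skf.split(np.zeros(len(condition)), condition)]


def _stratified_resample(
    trials: TrialBetaMatrix, rng: np.random.Generator, by_run: bool
) -> TrialBetaMatrix:
    """Resample trials with replacement, stratified by class (and by run for
    run-based schemes, preserving every run's class composition)."""
    keep = []
    strata = (
        [(c, r) for c in trials.classes for r in np.unique(trials.run)]
        if by_run
        else [(c, None) for c in trials.classes]
    )
    for c, r in strata:
        mask = trials.condition == c
        if r is not None:
            mask &= trials.run == r
        idx = np.flatnonzero(mask)
        if len(idx):
            keep.append(rng.choice(idx, size=len(idx), replace=True))
    return trials.subset(np.sort(np.concatenate(keep)))


def _score_fold_outputs(fold_outputs, metric: str, pooled: bool) -> list[float]:
    def one(chunks):
        margins = np.concatenate([m for m, _, _ in chunks])
        preds = np.concatenate([p for _, p, _ in chunks])
        trues = np.concatenate([t for _, _, t in chunks])
        if metric == "auc":
            return auc_score(margins, trues)
        return float(np.mean(preds == trues))

    if pooled:
        return [one(fold_outputs)]
    return [one([fo]) for fo in fold_outputs]


def cv_decode(
    trials: TrialBetaMatrix,
    scheme: str = "leave_one_run_out",
    k: int = 5,
    n_repeats: int = 1,
    n_boot: int = 100,
    n_components: int | None = None,
    seed: int = 0,
    metric: str = "auc",
) -> DecodingResult:
    """Binary condition decoding under LORO or (repeated) k-fold CV.

    Each bootstrap iteration resamples trials with replacement (stratified
    by class, and by run under LORO), balances classes by undersampling,
    runs the full cross-validation with PCA + linear SVM per fold, pools
    the held-out predictions, and scores them.  ``per_iteration`` has
    length ``n_boot``; with ``n_boot=1`` resampling is skipped and the
    individual fold scores are returned instead (length ``k * n_repeats``
    or the number of runs).
    """
    if scheme not in ("leave_one_run_out", "kfold"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if metric not in ("auc", "accuracy"):
        raise ValueError(f"unknown metric {metric!r}")
    classes = trials.classes
    if len(classes) != 2:
        raise ValueError(f"binary decoding needs exactly 2 classes, got {list(classes)}")
    run_based = scheme == "leave_one_run_out"
    if run_based and len(np.unique(trials.run)) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    rng = np.random.default_rng(seed)
    positive = classes[1]

    scores: list[float] = []
    for _ in range(n_boot):
        it = trials if n_boot == 1 else _stratified_resample(trials, rng, by_run=run_based)
        it = undersample(it, seed=int(rng.integers(2**31)), per_run=run_based)
        if run_based:
            folds = _loro_folds(it.run)
            fold_outputs = _pooled_scores(it, folds, n_components, positive)
            scores.extend(_score_fold_outputs(fold_outputs, metric, pooled=n_boot > 1))
        else:
            for _rep in range(n_repeats if n_boot == 1 else 1):
                folds = _kfold_folds(it.condition, k, rng)
                fold_outputs = _pooled_scores(it, folds, n_components, positive)
                scores.extend(_score_fold_outputs(fold_outputs, metric, pooled=n_boot > 1))
    per_iter = np.asarray(scores)
    return DecodingResult(metric=metric, per_iteration=per_iter, mean=float(per_iter.mean()), chance=0.5)


def cross_modal_decode(
    train: TrialBetaMatrix,
    test: TrialBetaMatrix,
    n_components: int | None = None,
    n_boot: int = 100,
    seed: int = 0,
    metric: str = "auc",
) -> DecodingResult:
    """Train on one modality, score on another; no leakage by construction.

    Per bootstrap iteration: the training modality is resampled (stratified
    by class) and balanced; the test modality is balanced and subsampled to
    match the training sample size; PCA + classifier are fitted on the
    training modality only and the held-out modality is scored.

    Passing the same object as ``train`` and ``test`` is allowed as a
    leakage-diagnostic mode (flagged with a warning): it reproduces
    within-modality training performance.
    """
    if train.n_features != test.n_features:
        raise ValueError(
            f"feature-dimension mismatch: train has {train.n_features}, "
            f"test has {test.n_features}"
        )
    if train is test:
        warnings.warn(
            "train and test are the same object: leakage-diagnostic mode",
            RuntimeWarning,
            stacklevel=2,
        )
    classes = train.classes
    if len(classes) != 2 or len(test.classes) != 2:
        raise ValueError("both modalities must contain exactly 2 classes")
    if not np.array_equal(classes, test.classes):
        raise ValueError("train and test must share class labels")
    rng = np.random.default_rng(seed)
    positive = classes[1]

    scores = []
    for _ in range(n_boot):
        tr = train if n_boot == 1 else _stratified_resample(train, rng, by_run=False)
        tr = undersample(tr, seed=int(rng.integers(2**31)), per_run=False)
        te = undersample(test, seed=int(rng.integers(2**31)), per_run=False)
        per_class = np.sum(tr.condition == positive)
        keep = []
        for c in classes:
            idx = np.flatnonzero(te.condition == c)
            keep.append(rng.choice(idx, size=per_class, replace=len(idx) < per_class))
        te = te.subset(np.sort(np.concatenate(keep)))

        pca, clf = fit_reducer_classifier(tr.patterns, tr.condition, n_components)
        reduced = pca.transform(te.patterns)
        if metric == "auc":
            margins = clf.decision_function(reduced)
            if clf.classes_[1] != positive:
                margins = -margins
            scores.append(auc_score(margins, te.condition == positive))
        else:
            scores.append(float(np.mean(clf.predict(reduced) == te.condition)))
    per_iter = np.asarray(scores)
    return DecodingResult(metric=metric, per_iteration=per_iter, mean=float(per_iter.mean()), chance=0.5)


def feature_decode_4class(
    trials: TrialBetaMatrix,
    feature: str,
    n_components: int | None = None,
    n_boot: int = 100,
    seed: int = 0,
) -> DecodingResult:
    """Four-class decoding: condition x median-split feature intensity.

    Ratings strictly above their median are "high", the rest (including
    exact-median ties) "low"; crossed with the two task conditions this
    yields four classes decoded under leave-one-run-out CV with one-vs-one
    linear classifiers and majority vote.  Metric is accuracy against a
    chance level of 0.25.
    """
    if feature not in trials.ratings:
        raise KeyError(
            f"feature {feature!r} has no ratings; available: {sorted(trials.ratings)}"
        )
    if len(trials.classes) != 2:
        raise ValueError("feature decoding needs exactly 2 task conditions")
    ratings = trials.ratings[feature]
    med = np.median(ratings)
    level = np.where(ratings > med, "high", "low")
    labels4 = np.char.add(np.char.add(trials.condition.astype(str), "_"), level)
    counts = {lab: int(n) for lab, n in zip(*np.unique(labels4, return_counts=True))}
    if len(counts) < 4:
        raise ValueError(f"median split emptied a class; counts: {counts}")

    four = TrialBetaMatrix(
        patterns=trials.patterns, condition=labels4, run=trials.run, ratings=trials.ratings
    )
    if len(np.unique(four.run)) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    rng = np.random.default_rng(seed)

    scores = []
    for _ in range(n_boot):
        it = four if n_boot == 1 else _stratified_resample(four, rng, by_run=False)
        it = undersample(it, seed=int(rng.integers(2**31)), per_run=False)
        fold_outputs = _pooled_scores(
            it, _loro_folds(it.run), n_components, positive=None
        )
        scores.extend(_score_fold_outputs(fold_outputs, "accuracy", pooled=n_boot > 1))
    per_iter = np.asarray(scores)
    return DecodingResult(
        metric="accuracy", per_iteration=per_iter, mean=float(per_iter.mean()), chance=0.25
    )
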