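"""RAKEL multilabel classification over a label-powerset transformation.

A sample here is a network node with a set of pathway-type labels out of a
fixed vocabulary of m labels. RAKEL (random k-labelsets) draws M random
size-k subsets of the label vocabulary and fits one label-powerset (LP)
classifier per subset: each sample's label set is restricted to the subset
and the restriction -- one of the observed label combinations -- becomes a
single multiclass target. At prediction time every member classifier's
predicted combination is expanded back into binary votes on the labels of
its subset; a label is assigned when the average vote across the members
covering it strictly exceeds the decision threshold (default 0.5).

Binary relevance (BR, one-vs-all) is the k = 1 special case with a full
singleton cover and is also provided directly.

Base learners are pluggable. The defaults mirror an SMO-trained support
vector machine with a polynomial or RBF kernel (multiclass handled
one-vs-one with vote aggregation, as in sklearn's SVC) and a random forest;
a 1-nearest-neighbour learner is available for small exact checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

BASE_KINDS = ("svm-poly", "svm-rbf", "rf", "knn")


@dataclass(frozen=True)
class BaseConfig:
    """Base single-label classifier configuration.

    kind: one of svm-poly (polynomial-kernel SVM, exponent E), svm-rbf
    (RBF-kernel SVM, width gamma), rf (random forest, n_trees) or knn
    (1-nearest-neighbour; exact-check oracle learner). C is the SVM
    regularization constant. standardize optionally z-scores features on
    the training split (off by default: diffusion-derived features share a
    common scale already).
    """

    kind: str = "svm-poly"
    C: float = 2.0
    exponent: int = 1
    gamma: float = 0.01
    n_trees: int = 100
    n_neighbors: int = 1
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.kind not in BASE_KINDS:
            raise ValueError(f"unknown base kind {self.kind!r}; expected {BASE_KINDS}")

    def make_estimator(self, seed: int):
        if self.kind == "svm-poly":
            return SVC(kernel="poly", degree=self.exponent, C=self.C,
                       gamma=1.0, coef0=1.0)
        if self.kind == "svm-rbf":
            return SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        if self.kind == "rf":
            return RandomForestClassifier(n_estimators=self.n_trees,
                                          random_state=seed)
        return KNeighborsClassifier(n_neighbors=self.n_neighbors,
                                    algorithm="brute")


@dataclass(frozen=True)
class LabelsetDraw:
    """The M size-k label subsets backing one RAKEL ensemble."""

    labelsets: tuple[tuple[int, ...], ...]
    seed: int

    def covered(self) -> set[int]:
        return {l for ls in self.labelsets for l in ls}


def validate_label_matrix(Y: np.ndarray, require_nonempty: bool = True) -> np.ndarray:
    Y = np.asarray(Y)
    if Y.ndim != 2:
        raise ValueError("label matrix must be 2-D")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("label matrix entries must be 0 or 1")
    if require_nonempty and (Y.sum(axis=1) == 0).any():
        raise ValueError("every training sample must carry at least one label")
    return Y.astype(np.int8)


def lp_transform(
    Y: np.ndarray, labelset: Sequence[int]
) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Label-powerset transformation restricted to one labelset.

    Each sample's class is its label set intersected with ``labelset``,
    encoded as a sorted tuple of label indices; the empty restriction is a
    legal class. Returns (class index per sample, class tuples in canonical
    sorted order); class index i maps to classes[i].
    """
    labelset = tuple(sorted(set(int(l) for l in labelset)))
    if not labelset:
        raise ValueError("labelset must be non-empty")
    Y = np.asarray(Y)
    restrictions = [
        tuple(l for l in labelset if Y[i, l]) for i in range(Y.shape[0])
    ]
    classes = sorted(set(restrictions))
    index = {c: j for j, c in enumerate(classes)}
    y = np.array([index[r] for r in restrictions], dtype=np.int64)
    return y, classes


def sample_labelsets(
    m: int, k: int, M: int, seed: int = 0, require_cover: bool = True
) -> LabelsetDraw:
    """Draw M random size-k subsets of {0, ..., m-1}.

    Subsets are drawn uniformly without replacement among the C(m, k)
    distinct k-subsets when that is possible (so C(m, k) <= M exhausts
    them), with replacement otherwise. When k * M >= m the draw is retried
    until the union covers every label, keeping the draw usable for
    full-vocabulary prediction; coverage of fewer labels is reported at fit
    time instead. Deterministic given the seed.
    """
    if not 1 <= k <= m:
        raise ValueError(f"k={k} must satisfy 1 <= k <= m={m}")
    if M < 1:
        raise ValueError("M must be at least 1")
    rng = np.random.default_rng(seed)
    n_subsets = math.comb(m, k)
    can_cover = k * M >= m
    for _ in range(1000):
        if n_subsets <= 100_000:
            pool = list(combinations(range(m), k))
            if n_subsets >= M:
                idx = rng.choice(n_subsets, size=M, replace=False)
            else:
                idx = rng.integers(0, n_subsets, size=M)
            draw = tuple(pool[i] for i in idx)
        else:  # astronomically many subsets; distinct draws near-certain
            draw = tuple(
                tuple(sorted(rng.choice(m, size=k, replace=False))) for _ in range(M)
            )
        if not can_cover or len({l for ls in draw for l in ls}) == m:
            return LabelsetDraw(draw, seed)
    raise RuntimeError("could not draw a covering labelset family")


@dataclass
class _Member:
    labelset: tuple[int, ...]
    classes: list[tuple[int, ...]]
    estimator: object | None  # None => constant predictor (single class)

    def predict_classes(self, X: np.ndarray) -> list[tuple[int, ...]]:
        if self.estimator is None:
            return [self.classes[0]] * X.shape[0]
        return [self.classes[j] for j in self.estimator.predict(X)]


@dataclass
class RakelModel:
    """Fitted RAKEL ensemble: labelset draw, M LP members, configuration."""

    draw: LabelsetDraw
    members: list[_Member]
    m: int
    base_config: BaseConfig
    threshold: float = 0.5
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None
    uncovered_labels: tuple[int, ...] = ()

    def _scale(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return X
        return (X - self.feature_mean) / self.feature_std


def rakel_fit(
    X: np.ndarray,
    Y: np.ndarray,
    k: int,
    M: int,
    base_config: BaseConfig | None = None,
    seed: int = 0,
    threshold: float = 0.5,
    labelsets: Sequence[Sequence[int]] | None = None,
) -> RakelModel:
    """Fit a RAKEL ensemble of M label-powerset classifiers.

    ``labelsets`` overrides the random draw (used for exact-enumeration
    checks and for the BR-equivalent singleton cover). Members whose LP
    transformation yields a single class are kept as constant predictors
    with a warning; labels carried by training samples but covered by no
    labelset are warned about at fit time and can never be predicted.
    """
    X = np.asarray(X, dtype=float)
    Y = validate_label_matrix(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    base_config = base_config or BaseConfig()
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    m = Y.shape[1]
    if labelsets is not None:
        draw = LabelsetDraw(
            tuple(tuple(sorted(set(int(l) for l in ls))) for ls in labelsets), seed
        )
        for ls in draw.labelsets:
            if not ls or not all(0 <= l < m for l in ls):
                raise ValueError(f"invalid labelset {ls} for m={m}")
    else:
        draw = sample_labelsets(m, k, M, seed)

    mean = std = None
    if base_config.standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        X = (X - mean) / std

    members: list[_Member] = []
    for ls in draw.labelsets:
        y, classes = lp_transform(Y, ls)
        if len(classes) == 1:
            warnings.warn(
                f"labelset {ls}: single LP class in training; member is constant"
            )
            members.append(_Member(ls, classes, None))
            continue
        est = base_config.make_estimator(seed)
        est.fit(X, y)
        members.append(_Member(ls, classes, est))

    present = set(np.flatnonzero(Y.sum(axis=0) > 0))
    uncovered = tuple(sorted(present - draw.covered()))
    if uncovered:
        warnings.warn(
            f"labels {uncovered} occur in training but are covered by no "
            f"labelset; they can never be predicted"
        )
    return RakelModel(draw, members, m, base_config, threshold, mean, std, uncovered)


def rakel_predict(
    model: RakelModel, X: np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """Threshold the per-label average vote across covering members.

    Each member votes 1 on the labels inside its predicted combination and
    0 on the rest of its labelset; labels outside a member's labelset get no
    vote from it. A label is assigned when its average vote strictly exceeds
    the threshold, so an exact tie is a negative decision. Samples may end
    up with an empty predicted set.
    """
    X = np.asarray(X, dtype=float)
    threshold = model.threshold if threshold is None else threshold
    X = model._scale(X)
    n = X.shape[0]
    votes = np.zeros((n, model.m))
    coverage = np.zeros(model.m)
    for member in model.members:
        coverage[list(member.labelset)] += 1
        for i, cls in enumerate(member.predict_classes(X)):
            for l in cls:
                votes[i, l] += 1
    out = np.zeros((n, model.m), dtype=np.int8)
    covered = coverage > 0
    avg = votes[:, covered] / coverage[covered]
    out[:, covered] = (avg > threshold).astype(np.int8)
    return out


@dataclass
class BrModel:
    """Binary-relevance model: one binary classifier per label."""

    estimators: list[object | None]  # None => constant predictor
    constants: list[int]
    m: int
    base_config: BaseConfig
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None

    def _scale(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return X
        return (X - self.feature_mean) / self.feature_std


def br_fit(
    X: np.ndarray, Y: np.ndarray, base_config: BaseConfig | None = None, seed: int = 0
) -> BrModel:
    """Fit one one-vs-all binary classifier per label.

    A label whose training column is constant gets a constant predictor
    (with a warning); otherwise the base learner is fitted on the binary
    column. Equivalent to RAKEL with k = 1 and a full singleton cover.
    """
    X = np.asarray(X, dtype=float)
    Y = validate_label_matrix(Y)
    base_config = base_config or BaseConfig()
    mean = std = None
    if base_config.standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        X = (X - mean) / std
    estimators: list[object | None] = []
    constants: list[int] = []
    for j in range(Y.shape[1]):
        col = Y[:, j]
        if col.min() == col.max():
            warnings.warn(f"label {j}: single class in training; constant predictor")
            estimators.append(None)
            constants.append(int(col[0]))
            continue
        est = base_config.make_estimator(seed)
        est.fit(X, col)
        estimators.append(est)
        constants.append(0)
    return BrModel(estimators, constants, Y.shape[1], base_config, mean, std)


def br_predict(model: BrModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    X = model._scale(X)
    out = np.zeros((X.shape[0], model.m), dtype=np.int8)
    for j, est in enumerate(model.estimators):
        if est is None:
            out[:, j] = model.constants[j]
        else:
            out[:, j] = est.predict(X)
    return out


def br_fit_predict(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    base_config: BaseConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Convenience: fit binary relevance on the training split and return
    predictions for the test split."""
    return br_predict(br_fit(X_train, Y_train, base_config, seed), X_test)


def save_model(model, path) -> None:
    import joblib

    joblib.dump(model, path)


def load_model(path):
    import joblib

    return joblib.load(path)
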