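"""Multilabel evaluation: the four measures, cross-validation and controls.

For true label sets L_i and predicted sets L_i' over m labels and n samples:

* accuracy     = mean_i |L_i & L_i'| / |L_i | L_i'|   (per-sample Jaccard)
* exact match  = fraction of samples with L_i' identical to L_i
* hamming loss = mean_i |L_i symmetric-difference L_i'| / m
* integrated score = accuracy * exact_match * (1 - hamming_loss)

The integrated score is the single model-selection criterion. Metrics are
always pooled over the out-of-fold predictions of a full cross-validation
pass (each sample predicted exactly once), not averaged per fold, because
the measures are defined over all n samples.

Also here: seeded ten-fold plans, repeated cross-validation, the
feature-permutation control (shuffling which node receives which feature
vector, within the chemical and/or enzyme block, labels fixed), parameter
grid search ranked by integrated score, and the separated-classification
ablation that trains chemicals and enzymes apart but pools their
out-of-fold predictions into one report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .multilabel import (
    BaseConfig,
    br_fit_predict,
    rakel_fit,
    rakel_predict,
    validate_label_matrix,
)

CHEMICAL = "chemical"
ENZYME = "enzyme"

_PERMUTE_MODES = ("all", "chemicals_only", "enzymes_only")


def integrated_score(accuracy: float, exact_match: float, hamming_loss: float) -> float:
    """Product measure accuracy * exact_match * (1 - hamming_loss)."""
    return accuracy * exact_match * (1.0 - hamming_loss)


@dataclass
class MetricsReport:
    """One evaluation run's accuracy, exact match, hamming loss and
    integrated score, with the sample and label counts they were pooled
    over. ``rounded`` gives the 3-decimal summary used in reports."""

    accuracy: float
    exact_match: float
    hamming_loss: float
    integrated_score: float
    n: int
    m: int

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {
            "accuracy": round(self.accuracy, ndigits),
            "exact_match": round(self.exact_match, ndigits),
            "hamming_loss": round(self.hamming_loss, ndigits),
            "integrated_score": round(self.integrated_score, ndigits),
        }


def multilabel_metrics(Y_true: np.ndarray, Y_pred: np.ndarray) -> MetricsReport:
    """Compute the four measures from binary true/predicted label matrices.

    Every true row must be non-empty (as in the training data); predicted
    rows may be empty, in which case the union is still non-empty and the
    sample's Jaccard term is zero.
    """
    Y_true = validate_label_matrix(Y_true, require_nonempty=True)
    Y_pred = validate_label_matrix(Y_pred, require_nonempty=False)
    if Y_true.shape != Y_pred.shape:
        raise ValueError(
            f"shape mismatch: true {Y_true.shape} vs predicted {Y_pred.shape}"
        )
    n, m = Y_true.shape
    T = Y_true.astype(bool)
    P = Y_pred.astype(bool)
    intersection = (T & P).sum(axis=1)
    union = (T | P).sum(axis=1)
    accuracy = float((intersection / union).mean())
    exact = float((intersection == union).mean())  # equal sets <=> |&| == |||
    hamming = float(((T ^ P).sum(axis=1) / m).mean())
    return MetricsReport(accuracy, exact, hamming,
                         integrated_score(accuracy, exact, hamming), n, m)


@dataclass(frozen=True)
class CvPlan:
    """Fold assignment per sample; fold sizes differ by at most one."""

    assignment: tuple[int, ...]
    folds: int
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignment) == fold)


def make_cv_plan(n: int, folds: int = 10, seed: int = 0) -> CvPlan:
    """Seeded uniform random partition into near-equal folds."""
    if n < folds:
        raise ValueError(f"cannot split n={n} samples into {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    sizes = [n // folds + (1 if f < n % folds else 0) for f in range(folds)]
    start = 0
    for f, size in enumerate(sizes):
        assignment[order[start:start + size]] = f
        start += size
    return CvPlan(tuple(int(a) for a in assignment), folds, seed)


class RakelStrategy:
    """Cross-validation strategy wrapping RAKEL fit + predict."""

    def __init__(self, k: int, M: int, base_config: BaseConfig | None = None,
                 seed: int = 0, threshold: float = 0.5):
        self.k = k
        self.M = M
        self.base_config = base_config or BaseConfig()
        self.seed = seed
        self.threshold = threshold

    def fit_predict(self, X_train, Y_train, X_test) -> np.ndarray:
        model = rakel_fit(X_train, Y_train, self.k, self.M, self.base_config,
                          seed=self.seed, threshold=self.threshold)
        return rakel_predict(model, X_test)


class BrStrategy:
    """Cross-validation strategy wrapping binary relevance."""

    def __init__(self, base_config: BaseConfig | None = None, seed: int = 0):
        self.base_config = base_config or BaseConfig()
        self.seed = seed

    def fit_predict(self, X_train, Y_train, X_test) -> np.ndarray:
        return br_fit_predict(X_train, Y_train, X_test, self.base_config, self.seed)


def cross_validate(X: np.ndarray, Y: np.ndarray, strategy, plan: CvPlan) -> MetricsReport:
    """Ten-fold (or k-fold) cross-validation, metrics pooled over folds.

    For every fold the strategy is fitted on the complementary samples and
    predicts the held-out fold; the four measures are computed once over the
    pooled out-of-fold predictions so each sample contributes exactly once.
    ``strategy`` is any object with fit_predict(X_train, Y_train, X_test).
    """
    X = np.asarray(X, dtype=float)
    Y = validate_label_matrix(Y)
    n = X.shape[0]
    if len(plan.assignment) != n:
        raise ValueError("cross-validation plan does not match sample count")
    predictions = np.zeros_like(Y)
    for fold in range(plan.folds):
        test_idx = plan.fold_indices(fold)
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        missing = np.flatnonzero(Y[train_mask].sum(axis=0) == 0)
        if missing.size:
            warnings.warn(
                f"fold {fold}: labels {missing.tolist()} absent from training; "
                f"unpredictable in this fold"
            )
        predictions[test_idx] = strategy.fit_predict(
            X[train_mask], Y[train_mask], X[test_idx]
        )
    return multilabel_metrics(Y, predictions)


def repeated_cv(
    X: np.ndarray,
    Y: np.ndarray,
    strategy,
    repeats: int = 100,
    base_seed: int = 0,
    folds: int = 10,
) -> tuple[list[MetricsReport], pd.DataFrame]:
    """Repeat cross-validation with plan seeds base_seed + repeat index.

    Returns the per-repeat reports plus a summary table with min, max, mean
    and standard deviation of each measure over the repeats.
    """
    reports = [
        cross_validate(X, Y, strategy, make_cv_plan(X.shape[0], folds, base_seed + r))
        for r in range(repeats)
    ]
    frame = pd.DataFrame(
        {
            "accuracy": [r.accuracy for r in reports],
            "exact_match": [r.exact_match for r in reports],
            "hamming_loss": [r.hamming_loss for r in reports],
            "integrated_score": [r.integrated_score for r in reports],
        }
    )
    summary = frame.agg(["min", "max", "mean", "std"]).T
    return reports, summary


def permute_features(
    X: np.ndarray, node_kinds: Sequence[str], mode: str, seed: int = 0
) -> np.ndarray:
    """Shuffle which node receives which feature vector, within kind blocks.

    ``mode`` selects the block(s): ``chemicals_only``, ``enzymes_only`` or
    ``all`` (both blocks, shuffled independently). Labels stay attached to
    nodes, so the control destroys the feature-label correspondence while
    preserving the multiset of feature rows.
    """
    if mode not in _PERMUTE_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_PERMUTE_MODES}")
    kinds = np.asarray(node_kinds)
    X = np.asarray(X, dtype=float)
    if kinds.shape[0] != X.shape[0]:
        raise ValueError("node_kinds does not match feature rows")
    rng = np.random.default_rng(seed)
    out = X.copy()
    blocks = []
    if mode in ("all", "chemicals_only"):
        blocks.append(np.flatnonzero(kinds == CHEMICAL))
    if mode in ("all", "enzymes_only"):
        blocks.append(np.flatnonzero(kinds == ENZYME))
    for idx in blocks:
        out[idx] = out[idx][rng.permutation(idx.size)]
    return out


DEFAULT_GRID: Mapping[str, Sequence] = {
    "dim": (50, 100, 150, 200, 250, 300),
    "k": tuple(range(2, 12)),
    "M": (5, 10),
    "C": (1, 2, 3),
    "E": (1, 2, 3),
}


def grid_search(
    features_by_dim: Mapping[int, np.ndarray],
    Y: np.ndarray,
    grid: Mapping[str, Sequence] | None = None,
    plan_seed: int = 0,
    folds: int = 10,
    base_kind: str = "svm-poly",
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive search over (dim, k, M, C, E), ranked by integrated score.

    Every combination is assessed by cross-validation under a shared plan
    seed. Ties are broken by accuracy, then by lexicographic configuration.
    Returns the best configuration and the full results table.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    dims = [d for d in grid["dim"] if d in features_by_dim]
    if not dims or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty parameter grid (or no features for any dim)")
    rows = []
    for dim, k, M, C, E in product(dims, grid["k"], grid["M"], grid["C"], grid["E"]):
        X = features_by_dim[dim]
        cfg = BaseConfig(kind=base_kind, C=C, exponent=E)
        strategy = RakelStrategy(k, M, cfg, seed=plan_seed)
        plan = make_cv_plan(X.shape[0], folds, plan_seed)
        report = cross_validate(X, Y, strategy, plan)
        rows.append({"dim": dim, "k": k, "M": M, "C": C, "E": E,
                     **report.rounded(12), "seed": plan_seed})
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["integrated_score", "accuracy", "dim", "k", "M", "C", "E"],
        ascending=[False, False, True, True, True, True, True],
        kind="mergesort",
    )
    best = ranked.iloc[0][["dim", "k", "M", "C", "E"]].to_dict()
    return {key: int(v) for key, v in best.items()}, table


def ablation_separate(
    X_chem: np.ndarray,
    X_enz: np.ndarray,
    Y_chem: np.ndarray,
    Y_enz: np.ndarray,
    strategy_factory: Callable[[], object],
    seed: int = 0,
    folds: int = 10,
) -> MetricsReport:
    """Classification strictly separated by node kind, pooled evaluation.

    Chemicals and enzymes are cross-validated independently (fresh strategy
    per group, shared plan seed) and the out-of-fold predictions of both
    groups are pooled before computing one report, so the result is directly
    comparable with the combined run on n_chem + n_enz samples.
    """
    for name, X, Y in (("chemical", X_chem, Y_chem), ("enzyme", X_enz, Y_enz)):
        if np.asarray(X).shape[0] == 0:
            raise ValueError(f"empty {name} group")
        if np.asarray(X).shape[0] != np.asarray(Y).shape[0]:
            raise ValueError(f"{name} group: features/labels sample mismatch")

    pooled_true = []
    pooled_pred = []
    for X, Y in ((X_chem, Y_chem), (X_enz, Y_enz)):
        X = np.asarray(X, dtype=float)
        Y = validate_label_matrix(Y)
        plan = make_cv_plan(X.shape[0], folds, seed)
        strategy = strategy_factory()
        predictions = np.zeros_like(Y)
        for fold in range(plan.folds):
            test_idx = plan.fold_indices(fold)
            train_mask = np.ones(X.shape[0], dtype=bool)
            train_mask[test_idx] = False
            predictions[test_idx] = strategy.fit_predict(
                X[train_mask], Y[train_mask], X[test_idx]
            )
        pooled_true.append(Y)
        pooled_pred.append(predictions)
    return multilabel_metrics(np.vstack(pooled_true), np.vstack(pooled_pred))


def write_metrics_tsv(reports: Sequence[MetricsReport], path, extra: Mapping | None = None) -> None:
    """Long-format TSV (repeat, metric, value) suitable for violin plots."""
    with open(path, "wt", encoding="utf-8") as fh:
        cols = "repeat\tmetric\tvalue"
        if extra:
            cols = "\t".join(extra.keys()) + "\t" + cols
        fh.write(cols + "\n")
        prefix = ("\t".join(str(v) for v in extra.values()) + "\t") if extra else ""
        for r, report in enumerate(reports):
            for metric, value in report.rounded(6).items():
                fh.write(f"{prefix}{r}\t{metric}\t{value}\n")
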