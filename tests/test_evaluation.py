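"""Multilabel measures, cross-validation machinery and controls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import accuracy_score, hamming_loss, jaccard_score

from hetpath.evaluation import (
    BrStrategy,
    RakelStrategy,
    ablation_separate,
    cross_validate,
    grid_search,
    integrated_score,
    make_cv_plan,
    multilabel_metrics,
    permute_features,
    repeated_cv,
)
from hetpath.multilabel import BaseConfig


class OracleStrategy:
    """Stub that memorizes the truth: predicts each sample's true labels."""

    def __init__(self, Y):
        self.Y = Y

    def fit_predict(self, X_train, Y_train, X_test):
        # recover test rows by matching feature rows (features are unique ids)
        idx = [int(x[0]) for x in X_test]
        return self.Y[idx]


class TestMetrics:
    def test_two_sample_worked_example(self):
        truth = np.array([[1, 1, 0], [0, 0, 1]])
        pred = np.array([[1, 0, 0], [0, 0, 1]])
        rep = multilabel_metrics(truth, pred)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.exact_match == pytest.approx(0.5)
        assert rep.hamming_loss == pytest.approx(1 / 6)
        assert rep.integrated_score == pytest.approx(0.3125)

    def test_perfect_predictions(self):
        Y = np.array([[1, 0], [0, 1], [1, 1]])
        rep = multilabel_metrics(Y, Y)
        assert (rep.accuracy, rep.exact_match, rep.hamming_loss,
                rep.integrated_score) == (1.0, 1.0, 0.0, 1.0)

    def test_single_label_miss_costs_two_over_m(self):
        # wrong single-label prediction: symmetric difference of size 2
        truth = np.array([[1, 0, 0, 0], [0, 1, 0, 0]])
        pred = np.array([[0, 1, 0, 0], [0, 1, 0, 0]])
        rep = multilabel_metrics(truth, pred)
        assert rep.hamming_loss == pytest.approx(0.5 * (2 / 4))

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(8)
        truth = (rng.random((40, 6)) < 0.4).astype(int)
        truth[truth.sum(axis=1) == 0, 0] = 1
        pred = (rng.random((40, 6)) < 0.4).astype(int)
        rep = multilabel_metrics(truth, pred)
        assert rep.hamming_loss == pytest.approx(hamming_loss(truth, pred))
        assert rep.exact_match == pytest.approx(accuracy_score(truth, pred))
        assert rep.accuracy == pytest.approx(
            jaccard_score(truth, pred, average="samples", zero_division=1)
        )

    @given(
        arrays(np.int8, (12, 5), elements=st.integers(0, 1)),
        arrays(np.int8, (12, 5), elements=st.integers(0, 1)),
    )
    def test_invariants(self, truth, pred):
        truth[truth.sum(axis=1) == 0, 0] = 1  # truth rows must be non-empty
        rep = multilabel_metrics(truth, pred)
        assert 0.0 <= rep.exact_match <= rep.accuracy <= 1.0
        assert 0.0 <= rep.hamming_loss <= 1.0
        assert rep.integrated_score == pytest.approx(
            integrated_score(rep.accuracy, rep.exact_match, rep.hamming_loss),
            abs=1e-12,
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            multilabel_metrics(np.ones((2, 2), dtype=int), np.ones((3, 2), dtype=int))


class TestCvPlan:
    def test_even_split(self):
        plan = make_cv_plan(20, 10, seed=0)
        sizes = [len(plan.fold_indices(f)) for f in range(10)]
        assert sizes == [2] * 10

    def test_remainder_distribution(self):
        plan = make_cv_plan(23, 10, seed=0)
        sizes = sorted(len(plan.fold_indices(f)) for f in range(10))
        assert sizes == [2] * 7 + [3] * 3

    def test_deterministic_and_partition(self):
        a = make_cv_plan(37, 10, seed=5)
        b = make_cv_plan(37, 10, seed=5)
        assert a == b
        covered = np.concatenate([a.fold_indices(f) for f in range(10)])
        assert sorted(covered) == list(range(37))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            make_cv_plan(5, 10)


class TestCrossValidate:
    @pytest.fixture
    def id_features(self):
        Y = (np.random.default_rng(0).random((30, 4)) < 0.4).astype(np.int8)
        Y[Y.sum(axis=1) == 0, 0] = 1
        X = np.arange(30, dtype=float)[:, None]
        return X, Y

    def test_oracle_stub_scores_perfectly(self, id_features):
        X, Y = id_features
        rep = cross_validate(X, Y, OracleStrategy(Y), make_cv_plan(30, 10, 1))
        assert rep.exact_match == 1.0 and rep.hamming_loss == 0.0

    def test_missing_label_in_fold_warns(self):
        Y = np.ones((20, 2), dtype=np.int8)
        Y[:, 1] = 0
        Y[3, 1] = 1  # label 1 exists in exactly one sample
        X = np.arange(20, dtype=float)[:, None]
        with pytest.warns(UserWarning, match="absent from training"):
            cross_validate(X, Y, OracleStrategy(Y), make_cv_plan(20, 10, 0))

    def test_repeated_cv_first_repeat_matches_single_run(self, id_features):
        X, Y = id_features
        strategy = OracleStrategy(Y)
        reports, summary = repeated_cv(X, Y, strategy, repeats=3, base_seed=11)
        single = cross_validate(X, Y, strategy, make_cv_plan(30, 10, 11))
        assert reports[0] == single
        assert set(summary.columns) == {"min", "max", "mean", "std"}


class TestPermuteFeatures:
    @pytest.fixture
    def blocks(self):
        rng = np.random.default_rng(2)
        X = rng.random((10, 3))
        kinds = np.array(["chemical"] * 6 + ["enzyme"] * 4)
        return X, kinds

    def test_chemicals_only_keeps_enzyme_rows(self, blocks):
        X, kinds = blocks
        out = permute_features(X, kinds, "chemicals_only", seed=3)
        assert np.array_equal(out[6:], X[6:])

    def test_enzymes_only_keeps_chemical_rows(self, blocks):
        X, kinds = blocks
        out = permute_features(X, kinds, "enzymes_only", seed=3)
        assert np.array_equal(out[:6], X[:6])

    @pytest.mark.parametrize("mode", ["all", "chemicals_only", "enzymes_only"])
    def test_row_multiset_preserved(self, blocks, mode):
        X, kinds = blocks
        out = permute_features(X, kinds, mode, seed=4)
        key = lambda A: sorted(map(tuple, np.round(A, 12)))
        assert key(out) == key(X)

    def test_single_row_blocks_unchanged(self):
        X = np.array([[1.0], [2.0]])
        kinds = np.array(["chemical", "enzyme"])
        assert np.array_equal(permute_features(X, kinds, "all", seed=0), X)

    def test_unknown_mode(self, blocks):
        X, kinds = blocks
        with pytest.raises(ValueError, match="mode"):
            permute_features(X, kinds, "everything", seed=0)


class TestGridSearch:
    def test_one_point_grid_returns_it(self, easy_benchmark, easy_features):
        grid = {"dim": (32,), "k": (5,), "M": (1,), "C": (2,), "E": (1,)}
        best, table = grid_search(
            {32: easy_features}, easy_benchmark.labels, grid, plan_seed=1
        )
        assert best == {"dim": 32, "k": 5, "M": 1, "C": 2, "E": 1}
        assert len(table) == 1

    def test_empty_grid_rejected(self, easy_features, easy_benchmark):
        with pytest.raises(ValueError, match="empty"):
            grid_search({32: easy_features}, easy_benchmark.labels,
                        {"dim": (), "k": (2,), "M": (5,), "C": (1,), "E": (1,)})


class TestAblationSeparate:
    def test_perfect_oracle_pools_to_perfect_report(self):
        rng = np.random.default_rng(0)
        Yc = (rng.random((20, 3)) < 0.5).astype(np.int8)
        Yc[Yc.sum(axis=1) == 0, 0] = 1
        Ye = (rng.random((15, 3)) < 0.5).astype(np.int8)
        Ye[Ye.sum(axis=1) == 0, 0] = 1
        Xc = np.arange(20, dtype=float)[:, None]
        Xe = np.arange(20, 35, dtype=float)[:, None]  # globally unique row ids
        Y_all = np.vstack([Yc, Ye])
        rep = ablation_separate(
            Xc, Xe, Yc, Ye,
            strategy_factory=lambda: OracleStrategy(Y_all),
            seed=1, folds=5,
        )
        assert rep.n == 35
        assert rep.exact_match == 1.0 and rep.integrated_score == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ablation_separate(
                np.zeros((0, 2)), np.ones((4, 2)),
                np.zeros((0, 2), dtype=int), np.ones((4, 2), dtype=int),
                strategy_factory=lambda: None,
            )


def test_combined_training_beats_separated_on_cross_kind_signal(
    easy_benchmark, easy_features
):
    """With label signal carried by cross-kind edges, pooling chemicals and
    enzymes for classification should not hurt the integrated score."""
    bench = easy_benchmark
    X, Y = easy_features, bench.labels
    cfg = BaseConfig(kind="svm-poly", C=2, exponent=1)
    make_strategy = lambda: RakelStrategy(Y.shape[1], 5, cfg, seed=1)
    combined = cross_validate(X, Y, make_strategy(), make_cv_plan(len(X), 10, 1))
    chem = np.asarray(bench.kinds) == "chemical"
    separated = ablation_separate(
        X[chem], X[~chem], Y[chem], Y[~chem], make_strategy, seed=1
    )
    assert combined.integrated_score >= separated.integrated_score
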