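"""Splitting, tuning, training, prediction, and the metric formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemlens.chemdata import ClassLabel
from chemlens.model import (
    ConfusionTally,
    ForestParams,
    HyperparameterGrid,
    TrainedModel,
    TreeStructure,
    assign_class,
    compute_metrics,
    metrics_from_tally,
    predict_probabilities,
    run_trials,
    stratified_split,
    summarize_trials,
    train_model,
    tune_hyperparameters,
)


def _labels(n_per_class, n_classes=4):
    return np.repeat(np.arange(n_classes), n_per_class)


class TestStratifiedSplit:
    def test_exact_division(self):
        y = _labels(100)
        plan = stratified_split(y, train_fraction=0.7, seed=0)
        for c in range(4):
            assert np.sum(y[plan.train_indices] == c) == 70
            assert np.sum(y[plan.test_indices] == c) == 30

    def test_deterministic(self):
        y = _labels(20)
        a = stratified_split(y, seed=5)
        b = stratified_split(y, seed=5)
        assert np.array_equal(a.train_indices, b.train_indices)

    def test_full_fraction_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(_labels(10), train_fraction=1.0, seed=0)

    def test_tiny_class_rejected(self):
        y = np.array([0, 0, 1, 1, 2, 2, 3])
        with pytest.raises(ValueError):
            stratified_split(y, seed=0)

    @pytest.mark.parametrize("n_per_class", [10, 33, 47])
    def test_stratification_within_rounding(self, n_per_class):
        y = _labels(n_per_class)
        plan = stratified_split(y, train_fraction=0.7, seed=1)
        for c in range(4):
            got = np.sum(y[plan.train_indices] == c)
            assert abs(got - round(n_per_class * 0.7)) <= 1


def _stump(bit, left_vec, right_vec, n_nodes=3):
    """A single-split tree: bit<=0.5 -> left leaf, else right leaf."""
    return TreeStructure(
        feature=np.array([bit, -1, -1]),
        threshold=np.array([0.5, np.nan, np.nan]),
        children_left=np.array([1, -1, -1]),
        children_right=np.array([2, -1, -1]),
        value=np.array([[0.25] * 4, left_vec, right_vec]),
    )


class TestPrediction:
    def test_single_tree_returns_leaf_vector(self):
        model = TrainedModel(
            trees=[_stump(0, [0.9, 0.1, 0, 0], [0, 0, 0.3, 0.7])],
            n_features=4, params=ForestParams(1, 1, 2), seed=0,
        )
        x = np.array([0, 1, 1, 0], dtype=float)
        probs = predict_probabilities(model, x)
        assert np.allclose(probs.p, [0.9, 0.1, 0, 0])

    def test_two_tree_averaging(self):
        model = TrainedModel(
            trees=[
                _stump(0, [1, 0, 0, 0], [1, 0, 0, 0]),
                _stump(0, [0, 1, 0, 0], [0, 1, 0, 0]),
            ],
            n_features=2, params=ForestParams(2, 1, 2), seed=0,
        )
        probs = predict_probabilities(model, np.array([0.0, 0.0]))
        assert np.allclose(probs.p, [0.5, 0.5, 0, 0])

    def test_probabilities_valid_for_random_inputs(self):
        rng = np.random.default_rng(0)
        X = (rng.random((60, 10)) < 0.5).astype(float)
        y = rng.integers(0, 4, 60)
        model = train_model(X, y, ForestParams(10, 1, 2), seed=0)
        proba = model.predict_proba_matrix(X)
        assert np.all(proba >= 0) and np.allclose(proba.sum(axis=1), 1.0)

    def test_feature_length_mismatch_rejected(self):
        model = TrainedModel(
            trees=[_stump(0, [1, 0, 0, 0], [0, 1, 0, 0])],
            n_features=4, params=ForestParams(1, 1, 2), seed=0,
        )
        with pytest.raises(ValueError):
            model.predict_proba_matrix(np.zeros((1, 7)))


class TestTraining:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = (rng.random((80, 12)) < 0.5).astype(float)
        y = rng.integers(0, 4, 80)
        Xq = (rng.random((20, 12)) < 0.5).astype(float)
        a = train_model(X, y, ForestParams(20, 1, 2), seed=3)
        b = train_model(X, y, ForestParams(20, 1, 2), seed=3)
        assert np.array_equal(a.predict_proba_matrix(Xq), b.predict_proba_matrix(Xq))

    def test_separable_toy_set_fit_perfectly(self):
        # class = index of the single indicator bit that is set
        X = np.kron(np.eye(4), np.ones((5, 1)))
        y = _labels(5)
        model = train_model(X, y, ForestParams(25, 1, 2), seed=0)
        assert np.array_equal(model.predict_codes(X), y)

    def test_leaf_vectors_are_distributions(self):
        rng = np.random.default_rng(2)
        X = (rng.random((50, 8)) < 0.5).astype(float)
        y = rng.integers(0, 4, 50)
        model = train_model(X, y, ForestParams(5, 1, 2), seed=0)
        for tree in model.trees:
            leaves = tree.value[tree.leaf_ids]
            assert np.all(leaves >= 0) and np.allclose(leaves.sum(axis=1), 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_model(np.zeros((10, 4)), np.zeros(10, dtype=int))

    def test_traversal_matches_sklearn_backend(self):
        rng = np.random.default_rng(3)
        X = (rng.random((60, 16)) < 0.4).astype(float)
        y = rng.integers(0, 4, 60)
        model = train_model(X, y, ForestParams(30, 2, 3), seed=1)
        Xq = (rng.random((40, 16)) < 0.4).astype(float)
        assert np.allclose(model.predict_proba_matrix(Xq), model._sklearn.predict_proba(Xq))

    def test_json_roundtrip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(4)
        X = (rng.random((40, 6)) < 0.5).astype(float)
        y = rng.integers(0, 4, 40)
        model = train_model(X, y, ForestParams(8, 1, 2), seed=0)
        path = tmp_path / "model.json"
        model.save_json(path)
        back = TrainedModel.load_json(path)
        assert np.allclose(model.predict_proba_matrix(X), back.predict_proba_matrix(X))


class TestAssignClass:
    def test_highest_probability_wins(self):
        from chemlens.model import ClassProbabilities

        assert assign_class(ClassProbabilities(np.array([0.37, 0.33, 0.20, 0.10]))) is ClassLabel.DT
        assert assign_class(ClassProbabilities(np.array([0.0, 0.0, 0.0, 1.0]))) is ClassLabel.R

    def test_tie_breaks_to_smallest_code(self):
        from chemlens.model import ClassProbabilities

        probs = ClassProbabilities(np.array([0.25, 0.25, 0.25, 0.25]))
        assert assign_class(probs) is ClassLabel.DT


class TestMetrics:
    def test_perfect_classifier(self):
        y = _labels(10)
        report = compute_metrics(y, y)
        for name in ("BA", "precision", "recall", "F1", "MCC"):
            assert report.macro[name] == 1.0

    def test_symmetric_tally_gives_zero_mcc(self):
        metrics, _ = metrics_from_tally(ConfusionTally(TP=25, FP=25, TN=25, FN=25))
        assert metrics["MCC"] == 0.0

    def test_printed_formula_values(self):
        metrics, degenerate = metrics_from_tally(ConfusionTally(TP=40, FP=10, TN=40, FN=10))
        assert metrics["MCC"] == pytest.approx(0.6, abs=1e-12)
        assert metrics["BA"] == pytest.approx(0.8, abs=1e-12)
        assert not degenerate

    def test_zero_denominator_flags_degenerate(self):
        metrics, degenerate = metrics_from_tally(ConfusionTally(TP=0, FP=0, TN=10, FN=5))
        assert degenerate and metrics["precision"] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0])

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_tallies_agree_with_naive_recount(self, pairs):
        pred = [p for p, _ in pairs]
        true = [t for _, t in pairs]
        report = compute_metrics(pred, true)
        for label in ClassLabel:
            c = label.code
            tp = sum(1 for p, t in pairs if p == c and t == c)
            fp = sum(1 for p, t in pairs if p == c and t != c)
            tn = sum(1 for p, t in pairs if p != c and t != c)
            fn = sum(1 for p, t in pairs if p != c and t == c)
            tally = report.tallies[label]
            assert (tally.TP, tally.FP, tally.TN, tally.FN) == (tp, fp, tn, fn)
            assert tally.total == len(pairs)


class TestTuning:
    def _separable(self, n=40):
        rng = np.random.default_rng(0)
        X = np.zeros((n, 8))
        y = _labels(n // 4)
        X[np.arange(n), y] = 1.0
        X[:, 4:] = (rng.random((n, 4)) < 0.5).astype(float)
        return X, y

    def test_single_combination_returned(self):
        X, y = self._separable()
        grid = HyperparameterGrid(min_samples_leaf=(2,), min_samples_split=(3,), n_trees=(10,))
        assert tune_hyperparameters(X, y, grid, seed=0) == ForestParams(10, 2, 3)

    def test_tie_breaks_lexicographically(self):
        # both grid points fit the separable toy task perfectly; the
        # lexicographically smaller (fewer trees) must win
        X, y = self._separable()
        grid = HyperparameterGrid(min_samples_leaf=(1,), min_samples_split=(2,), n_trees=(50, 25))
        assert tune_hyperparameters(X, y, grid, seed=0).n_trees == 25

    def test_choice_maximizes_inner_validation_score(self, benchmark_run):
        # exhaustive re-scoring oracle on a subsample of the planted-motif
        # benchmark: the returned point must beat or match every grid point
        X, y = benchmark_run["X"], benchmark_run["y"]
        keep = np.concatenate([np.flatnonzero(y == c)[:30] for c in range(4)])
        Xs, ys = X[keep], y[keep]
        grid = HyperparameterGrid(min_samples_leaf=(1, 10), min_samples_split=(2,), n_trees=(25, 50))
        chosen, scores = tune_hyperparameters(Xs, ys, grid, seed=0, return_scores=True)
        from chemlens.model import compute_metrics as cm, train_model as tm, stratified_split as ss

        inner = ss(ys, 0.7, seed=0)
        for params in grid.combinations():
            model = tm(Xs[inner.train_indices], ys[inner.train_indices], params, seed=0)
            score = cm(model.predict_codes(Xs[inner.test_indices]), ys[inner.test_indices]).macro["BA"]
            assert scores[params] == pytest.approx(score)
            assert scores[chosen] >= score

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            HyperparameterGrid(min_samples_leaf=(), min_samples_split=(), n_trees=()).combinations()

    def test_default_grid_is_full_cartesian_product(self):
        assert len(HyperparameterGrid().combinations()) == 80


class TestTrials:
    def test_single_trial_summary_equals_its_metrics(self):
        rng = np.random.default_rng(0)
        X = (rng.random((60, 10)) < 0.5).astype(float)
        y = _labels(15)
        results = run_trials(X, y, n_trials=1, base_seed=0, grid=None)
        summary = summarize_trials(results)
        assert summary["BA"]["median"] == results[0].metrics.macro["BA"]

    def test_deterministic_given_base_seed(self):
        rng = np.random.default_rng(1)
        X = (rng.random((40, 8)) < 0.5).astype(float)
        y = _labels(10)
        a = run_trials(X, y, n_trials=2, base_seed=4, grid=None)
        b = run_trials(X, y, n_trials=2, base_seed=4, grid=None)
        assert [r.metrics.macro for r in a] == [r.metrics.macro for r in b]

    def test_trial_seeds_increment_from_base(self):
        rng = np.random.default_rng(2)
        X = (rng.random((40, 8)) < 0.5).astype(float)
        y = _labels(10)
        results = run_trials(X, y, n_trials=3, base_seed=7, grid=None)
        assert [r.seed for r in results] == [7, 8, 9]

    def test_label_noise_never_helps(self, benchmark_run):
        # structural label noise decouples motifs from labels; median macro
        # BA must be non-increasing over matched seeds as noise grows
        from chemlens.fingerprints import fingerprint_matrix
        from chemlens.synthetic_data import BenchmarkSpec, generate_benchmark

        medians = []
        for noise in (0.0, 0.3, 0.6):
            spec = BenchmarkSpec(n_per_class=30, noise=noise, seed=11)
            ds = generate_benchmark(spec)
            X, _ = fingerprint_matrix(ds.entries)
            y = np.asarray(ds.labels_as_codes())
            results = run_trials(X, y, n_trials=3, base_seed=0, grid=None)
            medians.append(summarize_trials(results)["BA"]["median"])
        assert medians[0] >= medians[1] >= medians[2]
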