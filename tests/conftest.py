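"""Shared fixtures: the planted-motif benchmark at study scale.

The session-scoped benchmark run (100 compounds per class, no structural
noise, seed 0, 10 independent trials with hyperparameter tuning over a
reduced grid) is computed once and reused by the end-to-end tests; the
tuning grid is kept to 8 points so the whole suite trains in minutes while
still exercising the inner-validation selection protocol.
"""

from __future__ import annotations

import numpy as np
import pytest

from chemlens.chemdata import ClassLabel
from chemlens.fingerprints import fingerprint_matrix
from chemlens.model import HyperparameterGrid, run_trials
from chemlens.shapley import InterventionalTreeShap
from chemlens.synthetic_data import BenchmarkSpec, benchmark_ground_truth, generate_benchmark

REDUCED_GRID = HyperparameterGrid(
    min_samples_leaf=(1, 5), min_samples_split=(2, 5), n_trees=(25, 100)
)


@pytest.fixture(scope="session")
def benchmark_run():
    """Benchmark (n=100/class, noise 0, seed 0), fingerprints, and 10 trials."""
    spec = BenchmarkSpec(n_per_class=100, noise=0.0, seed=0)
    dataset = generate_benchmark(spec)
    ground_truth = {t.source_id: t for t in benchmark_ground_truth(spec, dataset)}
    X, fps = fingerprint_matrix(dataset.entries)
    y = np.asarray(dataset.labels_as_codes())
    trials = run_trials(X, y, n_trials=10, base_seed=0, grid=REDUCED_GRID)
    return {
        "spec": spec,
        "dataset": dataset,
        "ground_truth": ground_truth,
        "X": X,
        "fps": fps,
        "y": y,
        "trials": trials,
    }


@pytest.fixture(scope="session")
def explainer0(benchmark_run):
    """Exact tree explainer for trial 0, with its full-training background."""
    trial = benchmark_run["trials"][0]
    Z = benchmark_run["X"][trial.split.train_indices]
    return InterventionalTreeShap(trial.model), Z, trial


@pytest.fixture(scope="session")
def small_molecules():
    """A handful of parsed structures used across unit tests."""
    from chemlens.chemdata import parse_structure

    return {
        "piperidine": parse_structure("C1CCNCC1"),
        "benzene": parse_structure("c1ccccc1"),
        "ethane": parse_structure("CC"),
        "methane": parse_structure("C"),
        "propane": parse_structure("CCC"),
    }


def correct_test_indices(benchmark_run, trial, label: ClassLabel) -> list[int]:
    """Dataset indices of correctly predicted test compounds of one class."""
    X, y = benchmark_run["X"], benchmark_run["y"]
    pred = trial.model.predict_codes(X[trial.split.test_indices])
    return [
        int(i)
        for i, p in zip(trial.split.test_indices, pred)
        if y[i] == label.code and p == label.code
    ]
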