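"""Multiclass random-forest training, tuning, and evaluation.

Protocol: 70/30 stratified train/test splits, 10 independent trials, and a
hyperparameter grid over the minimum samples per leaf (1, 2, 5, 10), the
minimum samples required to split (2, 3, 5, 10), and the number of trees
(25, 50, 100, 200, 400) — the full 80-point Cartesian product — scored by
macro balanced accuracy on an inner 70/30 validation split of the training
partition.  Trained forests are exported to a backend-independent tree
structure (split feature, threshold, children, per-class leaf vectors) that
the Shapley module traverses on its own.

Metrics are computed one-vs-rest per class from first-principles confusion
tallies: BA = (TPR + TNR)/2, precision, recall, F1, and
MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
macro-averaged over the four classes.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit

from chemlens.chemdata import CLASS_ORDER, ClassLabel
from chemlens.fingerprints import Fingerprint

N_CLASSES = len(CLASS_ORDER)


@dataclass
class SplitPlan:
    """A stratified train/test partition of dataset indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        overlap = set(map(int, self.train_indices)) & set(map(int, self.test_indices))
        if overlap:
            raise ValueError("train and test indices overlap")


def stratified_split(y: Sequence[int], train_fraction: float = 0.7, seed: int = 0) -> SplitPlan:
    """Per-class random split at ``train_fraction``; deterministic given seed."""
    y = np.asarray(y)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1): an empty partition is disallowed")
    classes, counts = np.unique(y, return_counts=True)
    for cls, n in zip(classes, counts):
        if n < 2:
            raise ValueError(f"class code {int(cls)} has fewer than 2 members")
    splitter = StratifiedShuffleSplit(n_splits=1, train_size=train_fraction, random_state=seed)
    train_idx, test_idx = next(splitter.split(np.zeros((len(y), 1)), y))
    return SplitPlan(np.sort(train_idx), np.sort(test_idx), seed=seed, train_fraction=train_fraction)


class ForestParams(NamedTuple):
    """One hyperparameter combination, in tie-break order."""

    n_trees: int
    min_samples_leaf: int
    min_samples_split: int


@dataclass(frozen=True)
class HyperparameterGrid:
    """The full tuning grid (Cartesian product, 80 combinations by default)."""

    min_samples_leaf: tuple[int, ...] = (1, 2, 5, 10)
    min_samples_split: tuple[int, ...] = (2, 3, 5, 10)
    n_trees: tuple[int, ...] = (25, 50, 100, 200, 400)

    def combinations(self) -> list[ForestParams]:
        """All grid points, ordered lexicographically by (n_trees, leaf, split)."""
        combos = [
            ForestParams(t, leaf, split)
            for t, leaf, split in itertools.product(
                sorted(self.n_trees), sorted(self.min_samples_leaf), sorted(self.min_samples_split)
            )
        ]
        if not combos:
            raise ValueError("empty hyperparameter grid")
        return combos


DEFAULT_PARAMS = ForestParams(n_trees=100, min_samples_leaf=1, min_samples_split=2)


@dataclass
class TreeStructure:
    """One decision tree as flat arrays; leaves hold per-class probability vectors."""

    feature: np.ndarray  # int, -1 at leaves
    threshold: np.ndarray  # float, NaN at leaves
    children_left: np.ndarray  # int, -1 at leaves
    children_right: np.ndarray
    value: np.ndarray  # (n_nodes, N_CLASSES) distributions; meaningful at leaves

    @property
    def leaf_ids(self) -> np.ndarray:
        return np.flatnonzero(self.feature < 0)

    def descend(self, X: np.ndarray) -> np.ndarray:
        """Leaf node id reached by each row of X."""
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            feats = self.feature[node]
            active = np.flatnonzero(feats >= 0)
            if active.size == 0:
                return node
            cur = node[active]
            go_left = X[active, self.feature[cur]] <= self.threshold[cur]
            node[active] = np.where(go_left, self.children_left[cur], self.children_right[cur])


@dataclass
class ClassProbabilities:
    """A four-class probability vector in the fixed DT/ST_A/ST_B/R order."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} probabilities")
        if np.any(self.p < -1e-12) or abs(float(self.p.sum()) - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")

    def __getitem__(self, label: ClassLabel) -> float:
        return float(self.p[label.code])


@dataclass
class TrainedModel:
    """A trained multiclass forest in backend-independent form.

    The ensemble prediction is the unweighted mean of per-tree leaf
    distributions; every leaf vector is non-negative and sums to 1.
    """

    trees: list[TreeStructure]
    n_features: int
    params: ForestParams
    seed: int
    class_codes: tuple[int, ...] = tuple(c.code for c in CLASS_ORDER)
    _sklearn: object = field(default=None, repr=False, compare=False)

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        acc = np.zeros((X.shape[0], N_CLASSES))
        for tree in self.trees:
            acc += tree.value[tree.descend(X)]
        return acc / len(self.trees)

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba_matrix(X)
        return proba.argmax(axis=1)  # ties -> smallest class code

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "params": self.params._asdict(),
            "seed": self.seed,
            "class_codes": list(self.class_codes),
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": [None if not math.isfinite(x) else x for x in t.threshold],
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "value": t.value.tolist(),
                }
                for t in self.trees
            ],
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "TrainedModel":
        trees = [
            TreeStructure(
                feature=np.asarray(t["feature"], dtype=np.int64),
                threshold=np.asarray(
                    [np.nan if x is None else x for x in t["threshold"]], dtype=np.float64
                ),
                children_left=np.asarray(t["children_left"], dtype=np.int64),
                children_right=np.asarray(t["children_right"], dtype=np.int64),
                value=np.asarray(t["value"], dtype=np.float64),
            )
            for t in data["trees"]
        ]
        return cls(
            trees=trees,
            n_features=int(data["n_features"]),
            params=ForestParams(**data["params"]),
            seed=int(data["seed"]),
            class_codes=tuple(data["class_codes"]),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()) + "\n")

    @classmethod
    def load_json(cls, path: str | Path) -> "TrainedModel":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def _extract_tree(sk_tree, sk_classes: np.ndarray) -> TreeStructure:
    """Convert one fitted sklearn tree into the portable structure.

    Leaf count vectors are normalized to class distributions and scattered
    into the fixed four-class order (classes absent from training get 0).
    """
    t = sk_tree.tree_
    counts = t.value[:, 0, :]  # (n_nodes, n_trained_classes); sklearn >=1.3 may pre-normalize
    row_sums = counts.sum(axis=1, keepdims=True)
    dist = counts / np.where(row_sums > 0, row_sums, 1.0)
    value = np.zeros((t.node_count, N_CLASSES))
    for j, code in enumerate(sk_classes):
        value[:, int(code)] = dist[:, j]
    return TreeStructure(
        feature=t.feature.astype(np.int64).copy(),
        threshold=t.threshold.astype(np.float64).copy(),
        children_left=t.children_left.astype(np.int64).copy(),
        children_right=t.children_right.astype(np.int64).copy(),
        value=value,
    )


def train_model(
    X: np.ndarray, y: Sequence[int], params: ForestParams = DEFAULT_PARAMS, seed: int = 0
) -> TrainedModel:
    """Fit a multiclass random forest and export it to portable tree form.

    Hyperparameters outside the tuning grid stay at the conventional
    random-forest defaults (bootstrap resampling, sqrt(n_features) features
    per split, unlimited depth); they are recorded in the run manifest.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    clf = RandomForestClassifier(
        n_estimators=params.n_trees,
        min_samples_leaf=params.min_samples_leaf,
        min_samples_split=params.min_samples_split,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    trees = [_extract_tree(est, clf.classes_) for est in clf.estimators_]
    return TrainedModel(
        trees=trees, n_features=X.shape[1], params=params, seed=seed, _sklearn=clf
    )


def predict_probabilities(model: TrainedModel, fp: Fingerprint | np.ndarray) -> ClassProbabilities:
    """Ensemble class probabilities for one fingerprint (mean of leaf vectors)."""
    x = fp.bits if isinstance(fp, Fingerprint) else np.asarray(fp)
    return ClassProbabilities(model.predict_proba_matrix(x.astype(np.float64))[0])


def assign_class(probs: ClassProbabilities) -> ClassLabel:
    """Highest-probability class; ties break toward the smallest class code."""
    return ClassLabel.from_code(int(np.argmax(probs.p)))


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ConfusionTally:
    """One-vs-rest confusion counts for a single class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


METRIC_NAMES = ("BA", "precision", "recall", "F1", "MCC")


def metrics_from_tally(tally: ConfusionTally) -> tuple[dict[str, float], bool]:
    """The five printed metric formulas evaluated on one tally.

    Zero-denominator ratios are reported as 0 and flag the result as
    degenerate rather than raising.
    """
    degenerate = False

    def ratio(num: float, den: float) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    tpr = ratio(tally.TP, tally.TP + tally.FN)
    tnr = ratio(tally.TN, tally.TN + tally.FP)
    mcc_den = math.sqrt(
        (tally.TP + tally.FP)
        * (tally.TP + tally.FN)
        * (tally.TN + tally.FP)
        * (tally.TN + tally.FN)
    )
    metrics = {
        "BA": 0.5 * (tpr + tnr),
        "precision": ratio(tally.TP, tally.TP + tally.FP),
        "recall": tpr,
        "F1": ratio(2 * tally.TP, 2 * tally.TP + tally.FP + tally.FN),
        "MCC": ratio(tally.TP * tally.TN - tally.FP * tally.FN, mcc_den),
    }
    return metrics, degenerate


@dataclass
class MetricsReport:
    """Per-class (one-vs-rest) and macro-averaged performance metrics."""

    per_class: dict[ClassLabel, dict[str, float]]
    macro: dict[str, float]
    tallies: dict[ClassLabel, ConfusionTally]
    degenerate: bool = False


def compute_metrics(predictions: Sequence[int], truths: Sequence[int]) -> MetricsReport:
    """Evaluate BA/precision/recall/F1/MCC, one-vs-rest per class, macro-averaged."""
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    per_class: dict[ClassLabel, dict[str, float]] = {}
    tallies: dict[ClassLabel, ConfusionTally] = {}
    degenerate = False
    for label in CLASS_ORDER:
        c = label.code
        tally = ConfusionTally(
            TP=int(np.sum((pred == c) & (true == c))),
            FP=int(np.sum((pred == c) & (true != c))),
            TN=int(np.sum((pred != c) & (true != c))),
            FN=int(np.sum((pred != c) & (true == c))),
        )
        metrics, deg = metrics_from_tally(tally)
        per_class[label] = metrics
        tallies[label] = tally
        degenerate |= deg
    macro = {
        name: float(np.mean([per_class[label][name] for label in CLASS_ORDER]))
        for name in METRIC_NAMES
    }
    return MetricsReport(per_class=per_class, macro=macro, tallies=tallies, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Tuning and trials


def tune_hyperparameters(
    X: np.ndarray,
    y: Sequence[int],
    grid: HyperparameterGrid = HyperparameterGrid(),
    seed: int = 0,
    return_scores: bool = False,
):
    """Choose forest hyperparameters on an inner 70/30 validation split.

    Every grid point is trained on the inner-train partition and scored by
    macro balanced accuracy on the inner-validation partition; the argmax
    is returned with a deterministic tie-break (lexicographically smallest
    (n_trees, min_samples_leaf, min_samples_split)).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    inner = stratified_split(y, train_fraction=0.7, seed=seed)
    Xi, yi = X[inner.train_indices], y[inner.train_indices]
    Xv, yv = X[inner.test_indices], y[inner.test_indices]
    best: ForestParams | None = None
    best_score = -np.inf
    scores: dict[ForestParams, float] = {}
    for params in grid.combinations():
        model = train_model(Xi, yi, params, seed=seed)
        report = compute_metrics(model.predict_codes(Xv), yv)
        score = report.macro["BA"]
        scores[params] = score
        if score > best_score:  # combos iterate smallest-first, so ties keep the first
            best, best_score = params, score
    if return_scores:
        return best, scores
    return best


@dataclass
class TrialResult:
    """Artifacts of one independent prediction trial."""

    trial: int
    seed: int
    split: SplitPlan
    params: ForestParams
    model: TrainedModel
    metrics: MetricsReport


def run_trials(
    X: np.ndarray,
    y: Sequence[int],
    n_trials: int = 10,
    base_seed: int = 0,
    grid: HyperparameterGrid | None = HyperparameterGrid(),
    train_fraction: float = 0.7,
) -> list[TrialResult]:
    """Run independent prediction trials; trial ``t`` uses seed ``base_seed + t``.

    Each trial: stratified 70/30 split, hyperparameter tuning on the
    training partition (skipped when ``grid`` is None, falling back to the
    documented defaults), final fit on the entire training partition, and
    evaluation on the held-out test partition.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    results = []
    for t in range(n_trials):
        seed = base_seed + t
        split = stratified_split(y, train_fraction=train_fraction, seed=seed)
        Xtr, ytr = X[split.train_indices], y[split.train_indices]
        params = DEFAULT_PARAMS if grid is None else tune_hyperparameters(Xtr, ytr, grid, seed=seed)
        model = train_model(Xtr, ytr, params, seed=seed)
        metrics = compute_metrics(model.predict_codes(X[split.test_indices]), y[split.test_indices])
        results.append(TrialResult(t, seed, split, params, model, metrics))
    return results


def summarize_trials(results: Sequence[TrialResult]) -> dict[str, dict[str, float]]:
    """Median and quartiles of each macro metric over trials (boxplot data)."""
    summary = {}
    for name in METRIC_NAMES:
        vals = np.array([r.metrics.macro[name] for r in results])
        summary[name] = {
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return summary
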