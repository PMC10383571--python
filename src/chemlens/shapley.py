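"""Exact interventional Shapley attributions for tree ensembles on binary features.

Feature attributions follow the interventional (marginal) game: for a
foreground fingerprint x, a background sample z and a tree T, the value of
a coalition S is T evaluated on the hybrid input that takes the features
in S from x and all others from z.  Attributions are the exact Shapley
values of that game, averaged over the background set and over the trees
of the ensemble (both averages are exact by linearity).  The per-class
base value is the mean model probability over the background, so local
accuracy holds: base_c + Σ_b φ[c][b] equals the model's class-c
probability for x.

Exactness without enumeration: on binary features every root-to-leaf path
imposes a bit requirement per tested feature.  Relative to a pair (x, z) a
path feature either agrees (x == z; the leaf is reachable only if the
requirement matches that shared value) or disagrees, in which case the
requirement picks a side: features that must come from the foreground
(set A) and features that must come from the background (set B).  The
game restricted to one leaf is the conjunction game u(S) = [A ⊆ S, B ∩ S = ∅],
whose Shapley values have the closed form

    φ_i = (a−1)! b! / (a+b)!        for i ∈ A,
    φ_j = −a! (b−1)! / (a+b)!       for j ∈ B,      a = |A|, b = |B|,

and 0 for all other features.  Summing leaf values weighted by these
coefficients gives the exact attribution in time linear in leaves × path
length, vectorized over the background set.

The independent oracle is :func:`brute_force_shapley`, a direct
enumeration of all coalitions.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from chemlens.chemdata import CLASS_ORDER, ClassLabel
from chemlens.fingerprints import Fingerprint
from chemlens.model import N_CLASSES, TrainedModel, TreeStructure

# ---------------------------------------------------------------------------
# Brute-force oracle


def brute_force_shapley(
    value_function: Callable[[frozenset[int]], float | np.ndarray], M: int
) -> np.ndarray:
    """Shapley values of an M-player game by full coalition enumeration.

    φ_i = Σ_{S ⊆ N∖{i}} |S|! (M−|S|−1)! / M! · (v(S ∪ {i}) − v(S)).

    ``value_function`` may return a scalar or a vector (then one Shapley
    vector per output component is returned, shape (M, k)).  Guarded to
    M ≤ 16; beyond that use the exact tree algorithm.
    """
    if M > 16:
        raise ValueError("M > 16: enumeration infeasible; use interventional_shap")
    if M < 0:
        raise ValueError("M must be non-negative")
    values = [np.atleast_1d(np.asarray(value_function(frozenset(_bits(mask)), ), dtype=np.float64))
              for mask in range(1 << M)]
    k = values[0].shape[0]
    weights = [math.factorial(s) * math.factorial(M - s - 1) / math.factorial(M) for s in range(M)]
    phi = np.zeros((M, k))
    for mask in range(1 << M):
        s = bin(mask).count("1")
        for i in range(M):
            if mask & (1 << i):
                continue
            phi[i] += weights[s] * (values[mask | (1 << i)] - values[mask])
    return phi if k > 1 else phi[:, 0]


def _bits(mask: int) -> list[int]:
    return [i for i in range(mask.bit_length()) if mask & (1 << i)]


# ---------------------------------------------------------------------------
# Path decomposition of a tree over binary features


@dataclass
class _TreePaths:
    """Leaf-path requirement matrices of one tree, restricted to binary inputs."""

    used_features: np.ndarray  # (U,) feature ids constrained on some path
    on_path: np.ndarray  # (L, U) bool
    req: np.ndarray  # (L, U) required bit value where on_path, else 0
    leaf_values: np.ndarray  # (L, C)
    max_constraints: int  # longest constrained path (bounds a+b)


def _decompose_tree(tree: TreeStructure) -> _TreePaths:
    """Enumerate root-to-leaf paths as bit requirements.

    On binary inputs a split with threshold outside (0, 1) sends both bit
    values one way: such an edge adds no requirement (taking the other edge
    is impossible and that subtree is pruned).  A path demanding both
    values of one feature is unreachable and dropped.
    """
    rows: list[tuple[dict[int, int], np.ndarray]] = []

    def walk(node: int, constraints: dict[int, int]) -> None:
        f = int(tree.feature[node])
        if f < 0:
            rows.append((dict(constraints), tree.value[node]))
            return
        thr = float(tree.threshold[node])
        # bit values routed left under "value <= thr"
        left_vals = [v for v in (0, 1) if v <= thr]
        for child, vals in (
            (int(tree.children_left[node]), left_vals),
            (int(tree.children_right[node]), [v for v in (0, 1) if v not in left_vals]),
        ):
            if not vals:
                continue  # unreachable subtree on binary inputs
            if len(vals) == 2:
                walk(child, constraints)
                continue
            v = vals[0]
            if f in constraints:
                if constraints[f] != v:
                    continue  # conflicting requirement: dead path
                walk(child, constraints)
            else:
                constraints[f] = v
                walk(child, constraints)
                del constraints[f]

    walk(0, {})
    used = sorted({f for cons, _ in rows for f in cons})
    col = {f: j for j, f in enumerate(used)}
    L, U = len(rows), len(used)
    on_path = np.zeros((L, U), dtype=bool)
    req = np.zeros((L, U), dtype=np.int8)
    leaf_values = np.zeros((L, N_CLASSES))
    max_constraints = 0
    for i, (cons, val) in enumerate(rows):
        for f, v in cons.items():
            on_path[i, col[f]] = True
            req[i, col[f]] = v
        leaf_values[i] = val
        max_constraints = max(max_constraints, len(cons))
    return _TreePaths(np.asarray(used, dtype=np.int64), on_path, req, leaf_values, max_constraints)


def _weight_tables(max_n: int) -> tuple[np.ndarray, np.ndarray]:
    """W_plus[a, b] = (a−1)! b! / (a+b)! (0 when a = 0); W_minus is its mirror."""
    fact = np.array([math.factorial(i) for i in range(2 * max_n + 2)], dtype=np.float64)
    wp = np.zeros((max_n + 1, max_n + 1))
    wm = np.zeros((max_n + 1, max_n + 1))
    for a in range(max_n + 1):
        for b in range(max_n + 1):
            if a >= 1:
                wp[a, b] = fact[a - 1] * fact[b] / fact[a + b]
            if b >= 1:
                wm[a, b] = fact[a] * fact[b - 1] / fact[a + b]
    return wp, wm


# ---------------------------------------------------------------------------
# Explanations


@dataclass
class ShapExplanation:
    """Per-class, per-bit attributions with per-class base values.

    ``phi`` has shape (n_classes, n_bits) in probability units; ``base`` is
    the mean background probability per class.  Local accuracy:
    ``base_c + phi[c].sum()`` equals the model's class-c probability of the
    foreground.
    """

    phi: np.ndarray
    base: np.ndarray
    foreground: Fingerprint
    background_size: int
    prediction: np.ndarray  # model class probabilities of the foreground

    def check_local_accuracy(self, atol: float = 1e-8) -> None:
        recon = self.base + self.phi.sum(axis=1)
        if not np.allclose(recon, self.prediction, atol=atol, rtol=0):
            raise AssertionError(
                f"local accuracy violated: reconstructed {recon}, model {self.prediction}"
            )
        if abs(recon.sum() - 1.0) > max(atol, 1e-8):
            raise AssertionError(f"class additivity violated: total {recon.sum()}")


class InterventionalTreeShap:
    """Reusable exact explainer: decomposes the ensemble's trees once."""

    def __init__(self, model: TrainedModel, check: bool = False):
        self.model = model
        self.check = check
        self._paths = [_decompose_tree(t) for t in model.trees]
        max_n = max((p.max_constraints for p in self._paths), default=0)
        self._wp, self._wm = _weight_tables(max_n)

    def explain(
        self, foreground: Fingerprint, background: Sequence[Fingerprint] | np.ndarray
    ) -> ShapExplanation:
        Z = _as_matrix(background, self.model.n_features)
        if Z.shape[0] == 0:
            raise ValueError("background must be non-empty")
        x = foreground.bits.astype(np.int8)
        if x.shape[0] != self.model.n_features:
            raise ValueError("foreground length does not match model")
        phi = np.zeros((N_CLASSES, self.model.n_features))
        n_bg = Z.shape[0]
        for paths in self._paths:
            U = paths.used_features
            if U.size == 0:
                continue
            xU = x[U]
            D = (Z[:, U].astype(np.int8) != xU)  # (n_bg, U) disagreement
            MA = paths.on_path & (paths.req == xU)  # feature must come from foreground
            MB = paths.on_path & (paths.req != xU)  # feature must come from background
            MAf = MA.astype(np.float64)
            MBf = MB.astype(np.float64)
            Df = D.astype(np.float64)
            a = (MAf @ Df.T).astype(np.intp)  # (L, n_bg)
            b = (MBf @ Df.T).astype(np.intp)
            # a leaf is dead for (x, z) if some agreed feature requires the other bit
            ok = (MBf @ (1.0 - Df).T) < 0.5
            wp = self._wp[a, b] * ok
            wm = self._wm[a, b] * ok
            for c in range(N_CLASSES):
                lv = paths.leaf_values[:, c][:, None]
                contrib_a = MAf.T @ (lv * wp)  # (U, n_bg)
                contrib_b = MBf.T @ (lv * wm)
                phi[c, U] += ((contrib_a - contrib_b) * Df.T).sum(axis=1) / n_bg
        phi /= len(self.model.trees)
        base = self.model.predict_proba_matrix(Z).mean(axis=0)
        prediction = self.model.predict_proba_matrix(x.astype(np.float64))[0]
        expl = ShapExplanation(
            phi=phi,
            base=base,
            foreground=foreground,
            background_size=n_bg,
            prediction=prediction,
        )
        if self.check:
            expl.check_local_accuracy()
        return expl


def _as_matrix(background: Sequence[Fingerprint] | np.ndarray, n_features: int) -> np.ndarray:
    if isinstance(background, np.ndarray):
        Z = background
    else:
        Z = np.stack([fp.bits for fp in background]) if len(background) else np.zeros((0, n_features))
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim == 1:
        Z = Z[None, :]
    if Z.shape[0] and Z.shape[1] != n_features:
        raise ValueError("background feature length does not match model")
    return Z


def interventional_shap(
    model: TrainedModel,
    foreground: Fingerprint,
    background: Sequence[Fingerprint] | np.ndarray,
    check: bool = False,
) -> ShapExplanation:
    """Exact interventional Shapley attributions for one foreground compound."""
    return InterventionalTreeShap(model, check=check).explain(foreground, background)


def make_ensemble_game(
    model: TrainedModel, x: np.ndarray, Z: np.ndarray, players: Sequence[int]
) -> Callable[[frozenset[int]], np.ndarray]:
    """The interventional coalition game as an explicit function (oracle input).

    v(S) = mean over background rows z of the ensemble probability of the
    hybrid input taking features ``players[i]`` for i ∈ S from x and all
    other features from z.  Player indices refer to positions in
    ``players``.
    """
    players = np.asarray(players, dtype=np.int64)
    x = np.asarray(x, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)

    def value(S: frozenset[int]) -> np.ndarray:
        hybrid = Z.copy()
        idx = players[sorted(S)]
        hybrid[:, idx] = x[idx]
        return model.predict_proba_matrix(hybrid).mean(axis=0)

    return value


def used_features(model: TrainedModel) -> list[int]:
    """Sorted feature ids split on by at least one tree of the ensemble."""
    feats: set[int] = set()
    for tree in model.trees:
        feats.update(int(f) for f in tree.feature if f >= 0)
    return sorted(feats)


# ---------------------------------------------------------------------------
# Present/absent partitioning and cumulative aggregation


@dataclass
class PresentAbsentSummary:
    """Per-class sums of attributions split by foreground bit value."""

    present_sum: np.ndarray  # (C,)
    absent_sum: np.ndarray  # (C,)


def partition_present_absent(expl: ShapExplanation) -> PresentAbsentSummary:
    """Split per-class attribution sums by whether the bit is set in the foreground."""
    present = expl.foreground.bits.astype(bool)
    return PresentAbsentSummary(
        present_sum=expl.phi[:, present].sum(axis=1),
        absent_sum=expl.phi[:, ~present].sum(axis=1),
    )


@dataclass
class CumulativeCell:
    """One class's cumulative present/absent attribution for one trial."""

    present: float | None
    absent: float | None
    n_compounds: int

    @property
    def empty(self) -> bool:
        return self.n_compounds == 0


@dataclass
class CumulativeShapSummary:
    """Cumulative attributions per class over correctly predicted test compounds."""

    cells: dict[ClassLabel, CumulativeCell] = field(default_factory=dict)


def cumulative_shap(
    model: TrainedModel,
    test_fps: Sequence[Fingerprint],
    test_labels: Sequence[int],
    background: Sequence[Fingerprint] | np.ndarray,
    aggregate: str = "mean",
    explainer: InterventionalTreeShap | None = None,
) -> CumulativeShapSummary:
    """Aggregate present/absent attribution sums over correct predictions.

    Only correctly predicted compounds contribute; each contributes the
    present/absent sums of its true (= predicted) class.  ``aggregate``
    selects the per-trial reduction over compounds: ``"mean"`` (default) or
    ``"sum"`` — the two readings differ only by the class-size factor.
    A class with no correct predictions yields an empty cell, not zero.
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    explainer = explainer or InterventionalTreeShap(model)
    X = np.stack([fp.bits for fp in test_fps]).astype(np.float64)
    predicted = model.predict_codes(X)
    labels = np.asarray(test_labels)
    buckets: dict[ClassLabel, list[tuple[float, float]]] = {c: [] for c in CLASS_ORDER}
    for i, fp in enumerate(test_fps):
        if predicted[i] != labels[i]:
            continue
        expl = explainer.explain(fp, background)
        pa = partition_present_absent(expl)
        c = int(labels[i])
        buckets[ClassLabel.from_code(c)].append(
            (float(pa.present_sum[c]), float(pa.absent_sum[c]))
        )
    reduce = np.mean if aggregate == "mean" else np.sum
    cells = {}
    for label, vals in buckets.items():
        if not vals:
            cells[label] = CumulativeCell(present=None, absent=None, n_compounds=0)
        else:
            arr = np.asarray(vals)
            cells[label] = CumulativeCell(
                present=float(reduce(arr[:, 0])),
                absent=float(reduce(arr[:, 1])),
                n_compounds=len(vals),
            )
    return CumulativeShapSummary(cells=cells)


def explanation_to_csv(
    expl: ShapExplanation, compound_id: str, path: str | Path, nonzero_only: bool = True
) -> None:
    """Export one explanation as tidy (compound, class, bit, phi) rows."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "class", "bit", "phi"])
        for label in CLASS_ORDER:
            row = expl.phi[label.code]
            bits = np.flatnonzero(row) if nonzero_only else np.arange(row.shape[0])
            for b in bits:
                writer.writerow([compound_id, label.name, int(b), repr(float(row[b]))])
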