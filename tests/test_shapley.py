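"""Brute-force Shapley oracle, exact tree attributions, and aggregation."""

import itertools
import math

import numpy as np
import pytest

from chemlens.chemdata import ClassLabel
from chemlens.fingerprints import Fingerprint
from chemlens.model import ForestParams, TrainedModel, TreeStructure, train_model
from chemlens.shapley import (
    ShapExplanation,
    brute_force_shapley,
    cumulative_shap,
    interventional_shap,
    make_ensemble_game,
    partition_present_absent,
    used_features,
)


def _fp(bits):
    return Fingerprint(bits=np.asarray(bits, dtype=np.uint8))


class TestBruteForce:
    def test_single_player(self):
        table = {frozenset(): 2.0, frozenset({0}): 5.0}
        phi = brute_force_shapley(lambda S: table[S], 1)
        assert phi[0] == pytest.approx(3.0)

    def test_additive_game_recovers_weights(self):
        w = [0.5, -1.0, 2.0, 0.25]
        phi = brute_force_shapley(lambda S: sum(w[i] for i in S), 4)
        assert np.allclose(phi, w)

    def test_three_player_game_matches_permutation_average(self):
        # independent oracle: average marginal contributions over all 3! orderings
        values = {(): 0.0, (0,): 1.0, (1,): 2.0, (2,): 0.5, (0, 1): 4.0,
                  (0, 2): 1.0, (1, 2): 3.5, (0, 1, 2): 6.0}

        def v(S):
            return values[tuple(sorted(S))]

        perm_phi = np.zeros(3)
        for order in itertools.permutations(range(3)):
            S = []
            for player in order:
                before = v(S)
                S.append(player)
                perm_phi[player] += v(S) - before
        perm_phi /= math.factorial(3)
        assert np.allclose(brute_force_shapley(v, 3), perm_phi)

    def test_efficiency(self):
        rng = np.random.default_rng(0)
        table = {frozenset(s): rng.normal() for s in
                 itertools.chain.from_iterable(itertools.combinations(range(5), k) for k in range(6))}
        phi = brute_force_shapley(lambda S: table[S], 5)
        assert phi.sum() == pytest.approx(table[frozenset(range(5))] - table[frozenset()], abs=1e-12)

    def test_enumeration_guard(self):
        with pytest.raises(ValueError):
            brute_force_shapley(lambda S: 0.0, 17)


def _stump(bit, left_vec, right_vec):
    return TreeStructure(
        feature=np.array([bit, -1, -1]),
        threshold=np.array([0.5, np.nan, np.nan]),
        children_left=np.array([1, -1, -1]),
        children_right=np.array([2, -1, -1]),
        value=np.array([[0.25] * 4, left_vec, right_vec]),
    )


class TestInterventionalShap:
    def test_background_equal_to_foreground_gives_zero_attributions(self):
        rng = np.random.default_rng(0)
        X = (rng.random((30, 6)) < 0.5).astype(float)
        y = rng.integers(0, 4, 30)
        model = train_model(X, y, ForestParams(5, 1, 2), seed=0)
        fg = _fp(X[0])
        expl = interventional_shap(model, fg, X[0][None, :], check=True)
        assert np.allclose(expl.phi, 0.0, atol=1e-14)
        assert np.allclose(expl.base, model.predict_proba_matrix(X[0][None, :])[0])

    def test_single_stump_solved_by_hand(self):
        left = [0.8, 0.2, 0.0, 0.0]
        right = [0.1, 0.1, 0.4, 0.4]
        model = TrainedModel(trees=[_stump(7, left, right)], n_features=10,
                             params=ForestParams(1, 1, 2), seed=0)
        fg = np.zeros(10, dtype=np.uint8)
        fg[7] = 1  # foreground goes right
        bg = np.zeros((1, 10))  # background goes left
        expl = interventional_shap(model, _fp(fg), bg, check=True)
        for c in range(4):
            assert expl.phi[c, 7] == pytest.approx(right[c] - left[c])
            others = np.delete(expl.phi[c], 7)
            assert np.allclose(others, 0.0)

    def test_dummy_bits_have_zero_attribution(self):
        model = TrainedModel(trees=[_stump(2, [1, 0, 0, 0], [0, 0, 0, 1])], n_features=6,
                             params=ForestParams(1, 1, 2), seed=0)
        rng = np.random.default_rng(1)
        fg = _fp((rng.random(6) < 0.5).astype(np.uint8))
        bg = (rng.random((4, 6)) < 0.5).astype(float)
        expl = interventional_shap(model, fg, bg)
        untested = [b for b in range(6) if b != 2]
        assert np.allclose(expl.phi[:, untested], 0.0)

    def test_matches_brute_force_on_small_ensembles(self):
        rng = np.random.default_rng(42)
        for case in range(20):
            X = (rng.random((30, 8)) < 0.5).astype(float)
            y = rng.integers(0, 4, 30)
            model = train_model(X, y, ForestParams(3, 1, 2), seed=case)
            fg_bits = (rng.random(8) < 0.5).astype(np.uint8)
            Z = (rng.random((6, 8)) < 0.5).astype(float)
            expl = interventional_shap(model, _fp(fg_bits), Z, check=True)
            players = used_features(model)
            game = make_ensemble_game(model, fg_bits.astype(float), Z, players)
            phi_bf = brute_force_shapley(game, len(players))
            assert np.abs(phi_bf - expl.phi[:, players].T).max() < 1e-10

    def test_class_additivity(self):
        rng = np.random.default_rng(7)
        X = (rng.random((40, 10)) < 0.5).astype(float)
        y = rng.integers(0, 4, 40)
        model = train_model(X, y, ForestParams(10, 1, 2), seed=0)
        for i in range(5):
            expl = interventional_shap(model, _fp(X[i].astype(np.uint8)), X[10:20])
            totals = expl.base + expl.phi.sum(axis=1)
            assert totals.sum() == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_of_equivalent_bits(self):
        # two trees giving bits 0 and 1 perfectly exchangeable roles
        t01 = _stump(0, [1, 0, 0, 0], [0, 1, 0, 0])
        t10 = _stump(1, [1, 0, 0, 0], [0, 1, 0, 0])
        model = TrainedModel(trees=[t01, t10], n_features=4,
                             params=ForestParams(2, 1, 2), seed=0)
        fg = _fp([1, 1, 0, 0])
        bg = np.zeros((1, 4))
        expl = interventional_shap(model, fg, bg)
        assert np.allclose(expl.phi[:, 0], expl.phi[:, 1])

    def test_background_mean_consistency(self):
        # attributions with background B equal the mean of per-sample attributions
        rng = np.random.default_rng(9)
        X = (rng.random((30, 8)) < 0.5).astype(float)
        y = rng.integers(0, 4, 30)
        model = train_model(X, y, ForestParams(5, 1, 2), seed=1)
        fg = _fp((rng.random(8) < 0.5).astype(np.uint8))
        Z = (rng.random((5, 8)) < 0.5).astype(float)
        whole = interventional_shap(model, fg, Z)
        singles = [interventional_shap(model, fg, Z[i][None, :]).phi for i in range(5)]
        assert np.allclose(whole.phi, np.mean(singles, axis=0), atol=1e-12)

    def test_empty_background_rejected(self):
        model = TrainedModel(trees=[_stump(0, [1, 0, 0, 0], [0, 1, 0, 0])], n_features=4,
                             params=ForestParams(1, 1, 2), seed=0)
        with pytest.raises(ValueError):
            interventional_shap(model, _fp([0, 0, 0, 0]), np.zeros((0, 4)))


class TestPresentAbsent:
    def _expl(self, phi, fg_bits):
        fg = _fp(fg_bits)
        C, B = phi.shape
        return ShapExplanation(phi=phi, base=np.zeros(4), foreground=fg,
                               background_size=1, prediction=phi.sum(axis=1))

    def test_all_zero_foreground_has_no_present_sum(self):
        phi = np.zeros((4, 6))
        phi[0, 3] = 0.2
        pa = partition_present_absent(self._expl(phi, [0] * 6))
        assert np.allclose(pa.present_sum, 0.0)
        assert pa.absent_sum[0] == pytest.approx(0.2)

    def test_two_term_partition(self):
        phi = np.zeros((4, 10))
        phi[1, 3] = 0.2   # present bit
        phi[1, 9] = -0.05  # absent bit
        fg = [0] * 10
        fg[3] = 1
        pa = partition_present_absent(self._expl(phi, fg))
        assert pa.present_sum[1] == pytest.approx(0.2)
        assert pa.absent_sum[1] == pytest.approx(-0.05)

    def test_partition_reconstructs_probability(self):
        rng = np.random.default_rng(3)
        X = (rng.random((30, 8)) < 0.5).astype(float)
        y = rng.integers(0, 4, 30)
        model = train_model(X, y, ForestParams(5, 1, 2), seed=0)
        for i in range(4):
            fg = _fp(X[i].astype(np.uint8))
            expl = interventional_shap(model, fg, X[10:16])
            pa = partition_present_absent(expl)
            recon = pa.present_sum + pa.absent_sum + expl.base
            assert np.allclose(recon, expl.prediction, atol=1e-8)


class TestCumulative:
    def _toy(self):
        # bit c is a perfect indicator of class c
        X = np.kron(np.eye(4), np.ones((6, 1)))
        y = np.repeat(np.arange(4), 6)
        model = train_model(X, y, ForestParams(10, 1, 2), seed=0)
        return model, X, y

    def test_single_correct_compound_is_the_cell_mean(self):
        model, X, y = self._toy()
        fg = [_fp(X[0].astype(np.uint8))]
        summary = cumulative_shap(model, fg, [0], X)
        cell = summary.cells[ClassLabel.DT]
        assert cell.n_compounds == 1 and cell.present is not None
        expl = interventional_shap(model, fg[0], X)
        pa = partition_present_absent(expl)
        assert cell.present == pytest.approx(float(pa.present_sum[0]))
        assert cell.absent == pytest.approx(float(pa.absent_sum[0]))

    def test_misclassified_compound_contributes_nothing(self):
        model, X, y = self._toy()
        fg = [_fp(X[0].astype(np.uint8))]
        # true label deliberately wrong -> prediction mismatch -> empty cells
        summary = cumulative_shap(model, fg, [3], X)
        assert summary.cells[ClassLabel.R].empty
        assert all(summary.cells[c].n_compounds == 0 for c in ClassLabel)

    def test_empty_class_flagged_not_zero(self):
        model, X, y = self._toy()
        fps = [_fp(row.astype(np.uint8)) for row in X[:6]]  # only DT compounds
        summary = cumulative_shap(model, fps, [0] * 6, X)
        assert summary.cells[ClassLabel.DT].n_compounds == 6
        assert summary.cells[ClassLabel.ST_A].empty
        assert summary.cells[ClassLabel.ST_A].present is None

    def test_sum_aggregate_is_mean_times_count(self):
        model, X, y = self._toy()
        fps = [_fp(row.astype(np.uint8)) for row in X[:6]]
        mean_summary = cumulative_shap(model, fps, [0] * 6, X, aggregate="mean")
        sum_summary = cumulative_shap(model, fps, [0] * 6, X, aggregate="sum")
        cell_m, cell_s = mean_summary.cells[ClassLabel.DT], sum_summary.cells[ClassLabel.DT]
        assert cell_s.present == pytest.approx(cell_m.present * cell_m.n_compounds)
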