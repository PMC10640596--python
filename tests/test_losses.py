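"""Weak-supervision loss terms against an independent scalar-loop oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octloc.losses import (
    EPS,
    loss_column_constraint,
    loss_flip_symmetry,
    loss_slice_bce,
    loss_total,
)
from octloc.nn import Tensor

LN2 = float(np.log(2.0))


# ----------------------------------------------------------- scalar oracles
def _clamp(p):
    return min(max(p, EPS), 1.0 - EPS)


def oracle_l1(yhat, y0):
    total = 0.0
    for b in range(yhat.shape[1]):
        p = _clamp(yhat[0, b])
        total += -(y0[b] * np.log(p) + (1 - y0[b]) * np.log(1 - p))
    return total


def oracle_l2(yhat, y0):
    c = yhat.shape[0] - 1
    total = 0.0
    for b in range(yhat.shape[1]):
        if y0[b] == 0:
            total += -sum(np.log(1 - _clamp(yhat[1 + i, b])) for i in range(c)) / c
        else:
            total += -max(np.log(_clamp(yhat[1 + i, b])) for i in range(c))
    return total


def _kl(p, q):
    return p * np.log(p / q) + (1 - p) * np.log((1 - p) / (1 - q))


def oracle_l3(yhat, yhat_flip):
    c = yhat.shape[0] - 1
    total = 0.0
    for b in range(yhat.shape[1]):
        for i in range(c):
            p = _clamp(yhat[1 + i, b])
            q = _clamp(yhat_flip[1 + (c - 1 - i), b])
            pf = _clamp(yhat_flip[1 + i, b])
            qf = _clamp(yhat[1 + (c - 1 - i), b])
            total += 0.5 * (_kl(p, q) + _kl(pf, qf))
    return total


class TestSliceBCE:
    def test_half_probability_single_marker(self):
        yhat = np.full((2, 1), 0.5)
        assert loss_slice_bce(yhat, np.array([1])) == pytest.approx(LN2, rel=1e-5)

    def test_sums_over_markers(self):
        yhat = np.full((3, 2), 0.5)
        assert loss_slice_bce(yhat, np.array([1, 0])) == pytest.approx(2 * LN2, rel=1e-5)

    def test_perfect_prediction_bounded_by_clamp(self):
        yhat = np.zeros((2, 2))
        yhat[0] = [1.0, 0.0]
        loss = loss_slice_bce(yhat, np.array([1, 0]))
        assert 0 <= loss <= 2 * -np.log(1 - EPS) + 1e-6

    def test_non_binary_label_rejected(self):
        with pytest.raises(ValueError):
            loss_slice_bce(np.full((2, 1), 0.5), np.array([0.3]))


class TestColumnConstraint:
    def test_absent_marker_all_zero_columns(self):
        yhat = np.zeros((3, 1))
        assert loss_column_constraint(yhat, np.array([0])) == pytest.approx(0.0, abs=1e-5)

    def test_present_marker_one_confident_column(self):
        yhat = np.zeros((3, 1))
        yhat[1, 0] = 1.0
        assert loss_column_constraint(yhat, np.array([1])) == pytest.approx(0.0, abs=1e-5)

    def test_absent_half_probabilities(self):
        yhat = np.full((3, 1), 0.5)
        assert loss_column_constraint(yhat, np.array([0])) == pytest.approx(LN2, rel=1e-5)

    def test_monotone_in_max_for_present_marker(self):
        base = np.full((5, 1), 0.2)
        losses = []
        for peak in (0.3, 0.6, 0.9):
            yhat = base.copy()
            yhat[2, 0] = peak
            losses.append(loss_column_constraint(yhat, np.array([1])))
        assert losses[0] > losses[1] > losses[2]

    def test_gradient_flows_to_argmax_column_only(self):
        t = Tensor(np.array([[[0.4], [0.3], [0.7], [0.7]]]), requires_grad=True)
        loss = loss_column_constraint(t, np.array([1]))
        loss.backward()
        g = t.grad[0, :, 0]
        assert g[0] == 0 and g[3] == 0  # slice row untouched, tie loser untouched
        assert g[2] != 0  # lowest-index max column receives the gradient


class TestFlipSymmetry:
    def test_zero_at_perfect_symmetry(self, rng):
        yhat = rng.uniform(0.1, 0.9, size=(9, 2))
        flipped = yhat.copy()
        flipped[1:] = flipped[1:][::-1]
        assert loss_flip_symmetry(yhat, flipped) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_half_is_zero(self):
        yhat = np.full((5, 2), 0.5)
        assert loss_flip_symmetry(yhat, yhat) == pytest.approx(0.0, abs=1e-6)

    def test_single_column_bernoulli_kl(self):
        yhat = np.array([[0.5], [0.8]])
        yhat_flip = np.array([[0.5], [0.2]])
        expected = 0.6 * np.log(4.0)  # symmetric Bernoulli KL of 0.8 vs 0.2
        assert loss_flip_symmetry(yhat, yhat_flip) == pytest.approx(expected, rel=1e-5)

    def test_symmetric_in_arguments(self, rng):
        a = rng.uniform(0.05, 0.95, size=(6, 2))
        b = rng.uniform(0.05, 0.95, size=(6, 2))
        assert loss_flip_symmetry(a, b) == pytest.approx(loss_flip_symmetry(b, a), rel=1e-5)

    def test_nonnegative(self, rng):
        for _ in range(20):
            a = rng.uniform(0.01, 0.99, size=(5, 2))
            b = rng.uniform(0.01, 0.99, size=(5, 2))
            assert loss_flip_symmetry(a, b) >= 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss_flip_symmetry(np.full((3, 1), 0.5), np.full((4, 1), 0.5))


class TestAgainstOracle:
    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_all_terms_match_scalar_loops(self, seed):
        rng = np.random.default_rng(seed)
        c = int(rng.integers(1, 9))
        b = int(rng.integers(1, 3))
        yhat = rng.uniform(0, 1, size=(1 + c, b))
        yhat_flip = rng.uniform(0, 1, size=(1 + c, b))
        y0 = rng.integers(0, 2, size=b)
        assert loss_slice_bce(yhat, y0) == pytest.approx(oracle_l1(yhat, y0), rel=1e-5)
        assert loss_column_constraint(yhat, y0) == pytest.approx(oracle_l2(yhat, y0), rel=1e-5)
        assert loss_flip_symmetry(yhat, yhat_flip) == pytest.approx(
            oracle_l3(yhat, yhat_flip), rel=1e-4, abs=1e-5
        )


class TestTotalLoss:
    def test_breakdown_sums(self, rng):
        yhat = rng.uniform(0.1, 0.9, size=(5, 2))
        yhat_f = rng.uniform(0.1, 0.9, size=(5, 2))
        y0 = np.array([1, 0])
        bd = loss_total(yhat, yhat_f, y0)
        assert bd.total == pytest.approx(bd.l1 + bd.l1_flip + bd.l2 + bd.l2_flip + bd.l3, rel=1e-5)

    def test_perfect_symmetric_prediction_near_zero(self):
        yhat = np.zeros((4, 1))
        yhat[0, 0] = 1.0
        yhat[2, 0] = 1.0
        flipped = yhat.copy()
        flipped[1:] = flipped[1:][::-1]
        bd = loss_total(yhat, flipped, np.array([1]))
        assert bd.total == pytest.approx(0.0, abs=1e-4)

    def test_ablation_subsets(self, rng):
        yhat = rng.uniform(0.1, 0.9, size=(5, 2))
        yhat_f = rng.uniform(0.1, 0.9, size=(5, 2))
        y0 = np.array([1, 0])
        only_l1 = loss_total(yhat, yhat_f, y0, terms=("l1",))
        assert only_l1.l2 == 0 and only_l1.l3 == 0
        assert only_l1.total == pytest.approx(only_l1.l1 + only_l1.l1_flip, rel=1e-5)
        l1l2 = loss_total(yhat, yhat_f, y0, terms=("l1", "l2"))
        assert l1l2.l3 == 0

    def test_invalid_subsets_rejected(self, rng):
        yhat = rng.uniform(0.1, 0.9, size=(5, 2))
        for bad in [(), ("l2",), ("l1", "l3"), ("l2", "l3")]:
            with pytest.raises(ValueError):
                loss_total(yhat, yhat, np.array([1, 0]), terms=bad)
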