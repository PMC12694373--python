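"""Adaptive focal loss: closed forms, branch structure, state dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafdet.afl import (
    AFLState, QualityTargets, afl_batch_loss, decay_factor,
    modulating_weight, update_auto_iou, varifocal_loss,
)
from leafdet.nn import Tensor


class TestDecayFactor:
    def test_zero_at_step_zero(self):
        assert decay_factor(0) == 0.0

    def test_approaches_delta_in_the_limit(self):
        assert decay_factor(10_000_000) == pytest.approx(0.999, abs=1e-9)

    def test_closed_form_at_one_time_constant(self):
        # delta * (1 - e^-1), evaluated independently
        assert decay_factor(2000) == pytest.approx(0.6314884382697291, rel=1e-12)

    def test_monotone_nondecreasing_and_bounded(self):
        vals = [decay_factor(i) for i in range(0, 20000, 37)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v < 0.999 for v in vals)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            decay_factor(-1)
        with pytest.raises(ValueError):
            decay_factor(1, lam=0.0)
        with pytest.raises(ValueError):
            decay_factor(1, delta=1.0)


class TestAutoIouUpdate:
    def test_first_update_collapses_to_batch_iou(self):
        s = update_auto_iou(AFLState(), 0.5)
        assert s.auto_iou == pytest.approx(0.5)
        assert s.i == 1

    def test_floor_binds_for_low_batch_iou(self):
        s = update_auto_iou(AFLState(), 0.05)
        assert s.auto_iou == 0.2

    def test_convex_combination_at_half_decay(self):
        # delta=0.5 with i >> lam makes D_i = 0.5 to double precision
        s = AFLState(i=1000, lam=1.0, delta=0.5, auto_iou=0.8, auto_iou_pre=0.8)
        s2 = update_auto_iou(s, 0.4)
        assert s2.auto_iou == pytest.approx(0.6, rel=1e-12)
        assert s2.auto_iou_pre == pytest.approx(0.8)

    def test_out_of_range_batch_iou_rejected(self):
        with pytest.raises(ValueError):
            update_auto_iou(AFLState(), 1.5)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_floor_holds_for_any_iou_sequence(self, seq):
        s = AFLState()
        for v in seq:
            s = update_auto_iou(s, v)
            assert s.auto_iou >= 0.2


class TestModulatingWeight:
    @pytest.mark.parametrize("q,auto,expected", [
        (0.3, 0.5, 1.0),                      # first branch: 0.3 <= 0.4
        (0.45, 0.5, np.exp(0.5)),             # middle branch
        (0.9, 0.5, np.exp(0.1)),              # third branch
        (0.5, 0.5, np.exp(0.5)),              # boundary: ">=" binds (third)
        (0.4, 0.5, 1.0),                      # boundary: "<=" binds (first)
    ])
    def test_branch_values(self, q, auto, expected):
        assert modulating_weight(q, auto) == pytest.approx(expected, rel=1e-9)

    def test_exactly_one_branch_fires_on_a_fine_grid(self):
        for auto in np.linspace(0.2, 1.0, 17):
            qs = np.unique(np.concatenate([
                np.linspace(0, 1, 201), [auto - 0.1, auto, np.nextafter(auto, 0),
                                         np.nextafter(auto - 0.1, 1)]]))
            qs = qs[(qs >= 0) & (qs <= 1)]
            first = qs <= auto - 0.1
            mid = (qs > auto - 0.1) & (qs < auto)
            third = qs >= auto
            assert np.all(first.astype(int) + mid.astype(int) + third.astype(int) == 1)
            w = modulating_weight(qs, auto)
            assert np.allclose(w[first], 1.0)
            assert np.allclose(w[mid], np.exp(1 - auto))
            assert np.allclose(w[third], np.exp(1 - qs[third]))

    def test_weights_bounded_and_third_branch_decreasing(self):
        for auto in np.linspace(0.2, 1.0, 9):
            q = np.linspace(0, 1, 101)
            w = modulating_weight(q, auto)
            assert np.all(w >= 1.0 - 1e-12)
            assert np.all(w <= np.exp(0.8) + 1e-12)
            third = q >= auto
            assert np.all(np.diff(w[third]) <= 1e-12)

    def test_range_checks(self):
        with pytest.raises(ValueError):
            modulating_weight(0.5, 0.1)
        with pytest.raises(ValueError):
            modulating_weight(1.5, 0.5)


class TestVarifocalLoss:
    def test_perfect_positive_vanishes(self):
        assert varifocal_loss(40.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_negative_at_zero_logit(self):
        assert varifocal_loss(0.0, 0.0) == pytest.approx(
            0.75 * 0.25 * np.log(2), rel=1e-9)

    def test_positive_at_zero_logit(self):
        assert varifocal_loss(0.0, 1.0) == pytest.approx(np.log(2), rel=1e-9)

    def test_nonnegative_everywhere(self, rng):
        x = rng.normal(scale=5, size=200)
        q = rng.uniform(0, 1, size=200)
        assert np.all(varifocal_loss(x, q) >= 0)

    def test_gamma_to_zero_limit_recovers_alpha_weight(self):
        # at q=0 the focal weight alpha * sigma^gamma -> alpha as gamma -> 0
        x = 1.3
        bce = np.log1p(np.exp(x)) - 0.0 * x
        got = varifocal_loss(x, 0.0, alpha=0.6, gamma=1e-8)
        assert got == pytest.approx(0.6 * bce, rel=1e-6)


class TestBatchLoss:
    def test_single_element_closed_form(self):
        # VFL(0, 0.9) = (0.75*0.25*0.1 + 0.9) * ln 2, weight e^{0.1}
        state = AFLState(auto_iou=0.5, auto_iou_pre=0.5)
        got = afl_batch_loss(QualityTargets(np.array([0.0]), np.array([0.9]), 0.5), state)
        expect = (0.75 * 0.25 * 0.1 + 0.9) * np.log(2) * np.exp(0.1)
        assert got == pytest.approx(expect, rel=1e-9)

    def test_all_low_quality_reduces_to_plain_varifocal_mean(self, rng):
        state = AFLState(auto_iou=0.8, auto_iou_pre=0.8)
        x = rng.normal(size=30)
        q = rng.uniform(0, 0.69, size=30)   # all <= auto_iou - 0.1
        got = afl_batch_loss(QualityTargets(x, q, 0.5), state)
        assert got == pytest.approx(float(np.mean(varifocal_loss(x, q))), rel=1e-12)

    def test_mean_invariance_under_duplication(self):
        state = AFLState(auto_iou=0.5, auto_iou_pre=0.5)
        one = afl_batch_loss(QualityTargets(np.array([0.3]), np.array([0.6]), 0.5), state)
        two = afl_batch_loss(QualityTargets(np.array([0.3, 0.3]),
                                            np.array([0.6, 0.6]), 0.5), state)
        assert one == pytest.approx(two, rel=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            afl_batch_loss(QualityTargets(np.array([]), np.array([]), 0.0),
                           AFLState())

    def test_gradient_is_weight_times_varifocal_gradient(self, rng):
        """The modulating weight must act as a constant in the gradient."""
        state = AFLState(auto_iou=0.5, auto_iou_pre=0.5)
        x = rng.normal(size=12)
        q = rng.uniform(0, 1, size=12)
        xt = Tensor(x, requires_grad=True)
        afl_batch_loss(QualityTargets(xt, q, 0.5), state).backward()
        w = modulating_weight(q, 0.5)
        eps = 1e-6
        for k in range(12):
            xp, xm = x.copy(), x.copy()
            xp[k] += eps
            xm[k] -= eps
            dvfl = (varifocal_loss(xp[k], q[k]) - varifocal_loss(xm[k], q[k])) / (2 * eps)
            expected = w[k] * dvfl / 12
            assert xt.grad[k] == pytest.approx(expected, rel=1e-4, abs=1e-9)
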