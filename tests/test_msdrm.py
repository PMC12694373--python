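"""MSDRM family: residual identities, merge equivalence, morphological filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafdet.msdrm import (
    DRB, DRBSpec, DWR, MSDRM, ConvBN, ConvBNAct,
    expand_dilated_kernel, maxmin_filter,
)
from leafdet.nn import Tensor, count_parameters, zero_parameters


class TestMaxMinFilter:
    def test_constant_map_gives_zero(self):
        x = np.full((1, 2, 6, 6), 3.7)
        assert np.abs(maxmin_filter(x, 3)).max() == 0.0

    def test_step_edge_response_hand_derived(self):
        # replicate-padded windows over [0,0,0,1,1,1]:
        # (0,0,0)(0,0,0)(0,0,1)(0,1,1)(1,1,1)(1,1,1) -> gradient [0,0,1,1,0,0]
        row = np.array([0, 0, 0, 1, 1, 1.0])[None, None, None, :]
        out = maxmin_filter(row, 3)[0, 0, 0]
        assert np.allclose(out, [0, 0, 1, 1, 0, 0])

    def test_invariant_to_constant_shift(self, rng):
        x = rng.normal(size=(1, 3, 8, 8))
        assert np.allclose(maxmin_filter(x, 3), maxmin_filter(x + 17.3, 3))

    def test_nonnegative_and_shape_preserving(self, rng):
        x = rng.normal(size=(2, 4, 9, 7))
        out = maxmin_filter(x, 5)
        assert out.shape == x.shape
        assert out.min() >= 0

    def test_translation_equivariance(self, rng):
        x = rng.normal(size=(1, 1, 12, 12))
        shifted = np.roll(x, 2, axis=3)
        out = maxmin_filter(x, 3)
        out_shifted = maxmin_filter(shifted, 3)
        # compare away from wrap-around and padding borders
        assert np.allclose(out_shifted[..., 2:-2, 4:-2],
                           np.roll(out, 2, axis=3)[..., 2:-2, 4:-2])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            maxmin_filter(np.zeros((1, 1, 4, 4)), 4)


class TestDilatedExpansion:
    def test_1d_toy_expansion(self):
        w = np.array([[1.0, 2.0, 3.0]])[None, None]  # (1,1,1,3)
        out = expand_dilated_kernel(w, 2)
        assert np.allclose(out[0, 0, 0], [1, 0, 2, 0, 3])

    def test_dilation_one_is_identity(self, rng):
        w = rng.normal(size=(2, 1, 3, 3))
        assert np.array_equal(expand_dilated_kernel(w, 1), w)


class TestDRB:
    def test_spec_receptive_field_invariant(self):
        with pytest.raises(ValueError):
            DRBSpec(channels=4, large_kernel=5, small_branches=((3, 3),))

    def test_zero_input_zero_output_in_eval(self, rng):
        drb = DRB(DRBSpec(channels=4), rng=rng)
        drb(Tensor(rng.normal(size=(2, 4, 8, 8))))  # populate stats
        drb.eval()
        for bn in [drb.large.bn] + [b.bn for b in drb.small]:
            bn.running_mean[:] = 0.0
            bn.beta.data[:] = 0.0
        out = drb(Tensor(np.zeros((1, 4, 8, 8)))).data
        assert np.abs(out).max() < 1e-12

    def test_single_branch_equals_dense_sliding_window_oracle(self, rng):
        """One 3x3/d1 depthwise branch with identity BN equals brute-force
        correlation computed by explicit window sums."""
        spec = DRBSpec(channels=2, large_kernel=3, small_branches=())
        drb = DRB(spec, rng=rng)
        drb.eval()
        drb.large.bn.running_mean[:] = 0.0
        drb.large.bn.running_var[:] = 1.0 - drb.large.bn.eps
        x = rng.normal(size=(1, 2, 6, 6))
        out = drb(Tensor(x)).data
        w = drb.large.conv.weight.data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        ref = np.zeros_like(out)
        for c in range(2):
            for i in range(6):
                for j in range(6):
                    ref[0, c, i, j] = np.sum(xp[0, c, i:i + 3, j:j + 3] * w[c, 0])
        assert np.allclose(out, ref, atol=1e-10)

    def test_impulse_support_confined_to_large_kernel_footprint(self, rng):
        drb = DRB(DRBSpec(channels=1, large_kernel=7), rng=rng)
        drb.eval()
        for branch in [drb.large] + drb.small:
            branch.bn.running_mean[:] = 0.0
            branch.bn.beta.data[:] = 0.0
        x = np.zeros((1, 1, 15, 15))
        x[0, 0, 7, 7] = 1.0
        out = drb(Tensor(x)).data[0, 0]
        nz = np.argwhere(np.abs(out) > 1e-12)
        assert np.all(np.abs(nz - 7) <= 3)  # inside the 7x7 window

    def test_merge_equivalence_on_50_random_inputs(self, rng):
        drb = DRB(DRBSpec(channels=6), rng=rng)
        drb(Tensor(rng.normal(size=(4, 6, 10, 10))))
        drb.eval()
        worst = 0.0
        for _ in range(50):
            x = rng.normal(size=(1, 6, 9, 9))
            a = drb(Tensor(x)).data
            b = drb.forward_merged(x).data
            worst = max(worst, np.abs(a - b).max() / max(np.abs(a).max(), 1e-12))
        assert worst < 1e-5

    def test_merge_requires_frozen_statistics(self, rng):
        drb = DRB(DRBSpec(channels=2), rng=rng)
        with pytest.raises(RuntimeError):
            drb.merge()

    def test_single_branch_identity_norm_merged_kernel_is_padded_original(self, rng):
        spec = DRBSpec(channels=2, large_kernel=7, small_branches=((3, 1),))
        drb = DRB(spec, rng=rng)
        drb.eval()
        for branch in [drb.large] + drb.small:
            branch.bn.running_mean[:] = 0.0
            branch.bn.running_var[:] = 1.0 - branch.bn.eps
        kernel, bias = drb.merge()
        small = drb.small[0].conv.weight.data
        expect = drb.large.conv.weight.data.copy()
        expect[:, :, 2:5, 2:5] += small
        assert np.allclose(kernel, expect, atol=1e-12)
        assert np.allclose(bias, 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_merge_equivalence_for_sampled_specs(self, seed):
        rng = np.random.default_rng(seed)
        large = int(rng.choice([5, 7, 9]))
        branches = []
        for _ in range(int(rng.integers(1, 4))):
            k = int(rng.choice([3, 5]))
            dmax = (large - 1) // (k - 1)
            branches.append((k, int(rng.integers(1, dmax + 1))))
        spec = DRBSpec(channels=int(rng.integers(1, 5)), large_kernel=large,
                       small_branches=tuple(branches),
                       depthwise=bool(rng.integers(0, 2)))
        drb = DRB(spec, rng=rng)
        drb(Tensor(rng.normal(size=(2, spec.channels, large + 3, large + 3))))
        drb.eval()
        x = rng.normal(size=(1, spec.channels, large + 2, large + 2))
        a = drb(Tensor(x)).data
        b = drb.forward_merged(x).data
        assert np.abs(a - b).max() / max(np.abs(a).max(), 1e-12) < 1e-5


class TestDWR:
    def test_shape_contract(self, rng):
        dwr = DWR(8, rng=rng)
        out = dwr(Tensor(rng.normal(size=(2, 8, 12, 12))))
        assert out.shape == (2, 8, 12, 12)

    def test_zero_weight_residual_identity(self, rng):
        dwr = zero_parameters(DWR(6, rng=rng))
        x = rng.normal(size=(2, 6, 9, 9))
        assert np.allclose(dwr(Tensor(x)).data, x)

    def test_single_path_matches_straight_line_composition(self, rng):
        """DWR with one d=1 path equals the same ops chained by hand."""
        dwr = DWR(4, dilations=(1,), rng=rng)
        x = Tensor(rng.normal(size=(1, 4, 8, 8)))
        got = dwr(x).data
        r = dwr.regional(x)
        ref = (x + dwr.fuse(dwr.paths[0](r))).data
        assert np.allclose(got, ref, atol=1e-10)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            DWR(4, rng=rng)(Tensor(np.zeros((1, 6, 8, 8))))


class TestMSDRM:
    def test_shape_contract(self, rng):
        m = MSDRM(16, rng=rng)
        out = m(Tensor(rng.normal(size=(2, 16, 16, 16))))
        assert out.shape == (2, 16, 16, 16)

    def test_zero_weight_residual_identity(self, rng):
        m = zero_parameters(MSDRM(8, rng=rng))
        x = rng.normal(size=(2, 8, 10, 10))
        assert np.allclose(m(Tensor(x)).data, x)

    def test_residual_gradient_identity_at_zero_weights(self, rng):
        m = zero_parameters(MSDRM(4, rng=rng))
        x = rng.normal(size=(1, 4, 6, 6))
        xt = Tensor(x, requires_grad=True)
        m(xt).sum().backward()
        assert np.allclose(xt.grad, np.ones_like(x))

    def test_parameter_count_matches_analytic_inventory(self, rng):
        C = 16
        m = MSDRM(C, rng=rng)

        def conv(cin, cout, k, groups=1):
            return cout * (cin // groups) * k * k

        bn = 2 * C
        regional = conv(C, C, 3) + bn
        local = conv(C, C, 3)
        # depthwise DRB: large k conv + bn, plus per-branch k conv + bn
        def drb(large, branches):
            total = conv(C, C, large, groups=C) + bn
            for k, _d in branches:
                total += conv(C, C, k, groups=C) + bn
            return total

        expected = (regional + local
                    + drb(5, ((3, 1), (3, 2)))
                    + drb(7, ((3, 1), (3, 2), (3, 3)))
                    + bn)  # shared BN
        assert count_parameters(m) == expected

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            MSDRM(8, rng=rng)(Tensor(np.zeros((1, 4, 8, 8))))
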