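"""Triplet attention and CBAM against naive loop oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (naive_channel_gate, naive_conv2d, naive_sigmoid,
                     naive_triplet, naive_z_pool)
from rtcb import attention, nn
from rtcb.attention import (CBAM, CBAMConfig, ChannelGate, SpatialGate,
                            TripletAttention, TripletConfig, rotate, z_pool)


def T(a):
    return nn.Tensor(np.asarray(a, dtype=np.float32))


def zero_weights(module):
    for p in module.parameters():
        p.data[:] = 0.0
    return module


class TestZPool:
    def test_constant_channels(self):
        x = np.zeros((1, 3, 2, 2), dtype=np.float32)
        x[0, 0], x[0, 1], x[0, 2] = 1, 2, 3
        out = z_pool(T(x)).data
        assert out.shape == (1, 2, 2, 2)
        np.testing.assert_array_equal(out[0, 0], np.full((2, 2), 3.0))
        np.testing.assert_array_equal(out[0, 1], np.full((2, 2), 2.0))

    def test_single_channel_max_equals_mean(self, rng):
        x = rng.standard_normal((2, 1, 3, 3)).astype(np.float32)
        out = z_pool(T(x)).data
        np.testing.assert_array_equal(out[:, 0], out[:, 1])

    def test_matches_loop_oracle(self, small_map):
        out = z_pool(T(small_map)).data
        np.testing.assert_allclose(out, naive_z_pool(small_map), atol=1e-5)

    def test_max_dominates_mean(self, rng):
        x = rng.standard_normal((2, 6, 4, 4)).astype(np.float32)
        out = z_pool(T(x)).data
        assert (out[:, 0] >= out[:, 1] - 1e-6).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            z_pool(T(np.zeros((1, 0, 2, 2))))


class TestRotate:
    def test_inverse_pair_identity(self, rng):
        x = rng.standard_normal((2, 3, 4, 5)).astype(np.float32)
        for axis in ("H", "W"):
            back = rotate(rotate(T(x), axis, "ccw"), axis, "cw").data
            np.testing.assert_array_equal(back, x)

    def test_axis_swap_shapes(self):
        x = T(np.zeros((1, 8, 4, 6)))
        assert rotate(x, "H", "ccw").shape == (1, 6, 4, 8)
        assert rotate(x, "W", "ccw").shape == (1, 4, 8, 6)

    def test_full_index_permutation(self):
        x = np.arange(24, dtype=np.float32).reshape(1, 2, 3, 4)
        rh = rotate(T(x), "H", "ccw").data
        rw = rotate(T(x), "W", "ccw").data
        for n in range(1):
            for c in range(2):
                for h in range(3):
                    for w in range(4):
                        assert rh[n, w, h, c] == x[n, c, h, w]
                        assert rw[n, h, c, w] == x[n, c, h, w]

    def test_unknown_axis_rejected(self, small_map):
        with pytest.raises(ValueError):
            rotate(T(small_map), "C", "ccw")
        with pytest.raises(ValueError):
            rotate(T(small_map), "H", "ccww")


class TestTripletAttention:
    def test_zero_state_returns_half_input(self, rng):
        block = zero_weights(TripletAttention())
        x = rng.standard_normal((2, 4, 5, 6)).astype(np.float32)
        np.testing.assert_allclose(block(T(x)).data, x / 2, atol=1e-6)

    def test_shape_preserved(self, rng):
        block = TripletAttention(rng=rng)
        x = rng.standard_normal((2, 16, 9, 7)).astype(np.float32)
        assert block(T(x)).shape == x.shape

    def test_matches_naive_reference(self, rng):
        cfg = TripletConfig(kernel_size=3)
        block = TripletAttention(cfg, rng=rng)
        x = rng.standard_normal((1, 4, 4, 4)).astype(np.float32)
        convs = [(c.weight.data, c.bias.data)
                 for c in (block.branch_h, block.branch_w, block.branch_c)]
        expected = naive_triplet(x.astype(np.float64), convs, pad=cfg.padding)
        np.testing.assert_allclose(block(T(x)).data, expected, atol=1e-5)

    def test_rotated_branch_is_plain_branch_conjugated_by_rotation(self, rng):
        # with shared kernels, the rotating branch equals the no-rotation
        # branch conjugated by the rotation: rot^-1(branch3(rot(x))) ==
        # branch1(x) — checks the rotate/gate/un-rotate composition order
        block = TripletAttention(TripletConfig(kernel_size=3), rng=rng)
        block.branch_h.weight.data = block.branch_c.weight.data.copy()
        block.branch_h.bias.data = block.branch_c.bias.data.copy()
        x = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
        branch1 = rotate(block._gated(rotate(T(x), "H", "ccw"), block.branch_h),
                         "H", "cw").data
        pre = T(np.ascontiguousarray(x.transpose(0, 3, 2, 1)))
        conjugated = block._gated(pre, block.branch_c).data.transpose(0, 3, 2, 1)
        np.testing.assert_allclose(branch1, conjugated, atol=1e-6)

    def test_wrong_branch_channels_rejected(self, rng):
        block = TripletAttention(rng=rng)
        block.branch_h.weight.data = np.zeros((1, 3, 7, 7), dtype=np.float32)
        with pytest.raises(ValueError):
            block(T(rng.standard_normal((1, 4, 5, 5))))


class TestCBAM:
    def test_channel_gate_constant_input(self):
        gate = ChannelGate(4, CBAMConfig(reduction=2))
        f = np.ones((2, 4, 3, 3), dtype=np.float32)
        # gap == gmp == 1 for every channel -> gate = sigma(2*MLP(1))
        g = gate(T(f)).data
        v = np.ones((2, 4), dtype=np.float32)
        h = np.maximum(v @ gate.fc1.weight.data + gate.fc1.bias.data, 0)
        expected = naive_sigmoid(2 * (h @ gate.fc2.weight.data + gate.fc2.bias.data))
        np.testing.assert_allclose(g[:, :, 0, 0], expected, atol=1e-6)

    def test_channel_gate_spatially_uniform_input(self, rng):
        gate = ChannelGate(6, CBAMConfig(reduction=3), rng=rng)
        vc = rng.standard_normal(6).astype(np.float32)
        f = np.broadcast_to(vc[None, :, None, None], (1, 6, 4, 4)).copy()
        g = gate(T(f)).data[0, :, 0, 0]
        expected = naive_channel_gate(f.astype(np.float64),
                                      gate.fc1.weight.data, gate.fc1.bias.data,
                                      gate.fc2.weight.data, gate.fc2.bias.data)
        np.testing.assert_allclose(g, expected[0], atol=1e-5)

    def test_channel_gate_matches_matrix_oracle(self, rng):
        gate = ChannelGate(8, CBAMConfig(reduction=4), rng=rng)
        f = rng.standard_normal((1, 8, 3, 3)).astype(np.float32)
        g = gate(T(f)).data[:, :, 0, 0]
        expected = naive_channel_gate(f.astype(np.float64),
                                      gate.fc1.weight.data, gate.fc1.bias.data,
                                      gate.fc2.weight.data, gate.fc2.bias.data)
        np.testing.assert_allclose(g, expected, atol=1e-5)

    def test_reduction_clamped_for_narrow_layers(self):
        gate = ChannelGate(4, CBAMConfig(reduction=16))
        assert gate.fc1.out_features == 1

    def test_spatial_gate_zero_kernel_gives_half(self, rng):
        gate = zero_weights(SpatialGate(CBAMConfig()))
        f = rng.standard_normal((1, 3, 5, 5)).astype(np.float32)
        np.testing.assert_allclose(gate(T(f)).data, 0.5, atol=1e-7)

    def test_spatial_gate_matches_conv_oracle(self, rng):
        cfg = CBAMConfig(spatial_kernel=3)
        gate = SpatialGate(cfg, rng=rng)
        f = rng.standard_normal((1, 3, 5, 5)).astype(np.float32)
        z = naive_z_pool(f.astype(np.float64))
        expected = naive_sigmoid(naive_conv2d(z, gate.conv.weight.data,
                                              gate.conv.bias.data, pad=1))
        np.testing.assert_allclose(gate(T(f)).data, expected, atol=1e-5)

    def test_even_spatial_kernel_rejected(self):
        with pytest.raises(ValueError):
            CBAMConfig(spatial_kernel=4)

    def test_identity_bypass_returns_input(self, rng):
        block = CBAM(8, identity_bypass=True, rng=rng)
        f = rng.standard_normal((2, 8, 4, 4)).astype(np.float32)
        np.testing.assert_array_equal(block(T(f)).data, f)

    def test_zero_state_returns_quarter_input(self, rng):
        block = zero_weights(CBAM(8))
        f = rng.standard_normal((1, 8, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(block(T(f)).data, f / 4, atol=1e-6)

    def test_composition_matches_gate_oracles(self, rng):
        cfg = CBAMConfig(reduction=4, spatial_kernel=3)
        block = CBAM(8, cfg, rng=rng)
        f = rng.standard_normal((1, 8, 4, 4)).astype(np.float32)
        cg = naive_channel_gate(f.astype(np.float64),
                                block.channel_gate.fc1.weight.data,
                                block.channel_gate.fc1.bias.data,
                                block.channel_gate.fc2.weight.data,
                                block.channel_gate.fc2.bias.data)
        f2 = f * cg[:, :, None, None]
        sg = naive_sigmoid(naive_conv2d(naive_z_pool(f2),
                                        block.spatial_gate.conv.weight.data,
                                        block.spatial_gate.conv.bias.data, pad=1))
        np.testing.assert_allclose(block(T(f)).data, f2 * sg, atol=1e-5)

    def test_shape_preserved(self, rng):
        block = CBAM(32, rng=rng)
        f = rng.standard_normal((2, 32, 7, 7)).astype(np.float32)
        assert block(T(f)).shape == f.shape


@settings(max_examples=20, deadline=None, derandomize=True)
@given(n=st.integers(1, 2), c=st.integers(1, 8),
       h=st.integers(3, 8), w=st.integers(3, 8), seed=st.integers(0, 100))
def test_blocks_preserve_shape_and_gates_stay_open(n, c, h, w, seed):
    """Shape preservation and strict (0,1) gate range over a shape grid."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, c, h, w)).astype(np.float32)
    trip = TripletAttention(TripletConfig(kernel_size=3), rng=rng)
    cb = CBAM(c, CBAMConfig(reduction=4, spatial_kernel=3), rng=rng)
    assert trip(T(x)).shape == x.shape
    assert cb(T(x)).shape == x.shape
    gate = cb.channel_gate(T(x)).data
    assert ((gate > 0) & (gate < 1)).all()
    sgate = cb.spatial_gate(T(x)).data
    assert ((sgate > 0) & (sgate < 1)).all()
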