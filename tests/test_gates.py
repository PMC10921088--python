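"""Oracle tests for the attention gate and wavelet gate math.

The DWT path is checked against PyWavelets' dwt2/idwt2 as an independent
reference; the attention gate against scalar evaluations of the additive
formula.
"""

import math

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from watunet.autograd import Tensor
from watunet.gates import (
    AttentionGateModule,
    AttentionGateParams,
    WaveletGateModule,
    attention_gate,
    dwt_bands,
    idwt_bands,
    swish,
    wavelet_gate,
)


class TestSwish:
    def test_zero(self):
        assert swish(0.0) == 0.0

    def test_large_positive_asymptote(self):
        assert swish(50.0) == pytest.approx(50.0, abs=1e-6)

    def test_minus_one(self):
        expected = -1.0 / (1.0 + math.exp(1.0))  # -1 * sigmoid(-1)
        assert swish(-1.0) == pytest.approx(expected, abs=1e-12)
        assert swish(-1.0) == pytest.approx(-0.26894, abs=1e-5)


class TestAttentionGate:
    def test_zero_weights_give_half_attenuation(self, rng):
        x = rng.normal(size=(3, 6, 6))
        g = rng.normal(size=(2, 6, 6))
        params = AttentionGateParams(
            w_x=np.zeros((3, 3)), w_g=np.zeros((3, 2)), w_s=np.zeros(3)
        )
        out = attention_gate(x, g, params)
        assert np.allclose(out, 0.5 * x)

    def test_saturation_limit_passes_x_through(self, rng):
        x = np.abs(rng.normal(size=(2, 4, 4))) + 0.5
        g = np.ones((2, 4, 4))
        big = 1e4
        params = AttentionGateParams(
            w_x=big * np.eye(2), w_g=big * np.eye(2), w_s=big * np.ones(2)
        )
        out = attention_gate(x, g, params)
        assert np.allclose(out, x, atol=1e-6)

    def test_single_pixel_scalar_formula(self):
        # W_x = W_g = W_s = 1, x = g = 1: a = sigmoid(swish(2))
        params = AttentionGateParams(w_x=[[1.0]], w_g=[[1.0]], w_s=[1.0])
        out, a = attention_gate(
            np.ones((1, 1, 1)), np.ones((1, 1, 1)), params, return_coefficients=True
        )
        s2 = 2.0 / (1.0 + math.exp(-2.0))  # swish(2)
        expected = 1.0 / (1.0 + math.exp(-s2))
        assert a[0, 0, 0] == pytest.approx(expected, abs=1e-9)
        assert out[0, 0, 0] == pytest.approx(expected, abs=1e-9)

    def test_coefficients_strictly_in_unit_interval(self, rng):
        params = AttentionGateParams.init(c_x=4, c_g=3, seed=0)
        x = rng.normal(size=(4, 8, 8))
        g = rng.normal(size=(3, 8, 8))
        out, a = attention_gate(x, g, params, return_coefficients=True)
        assert np.all(a > 0) and np.all(a < 1)
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)

    def test_spatial_mismatch_rejected(self, rng):
        params = AttentionGateParams.init(c_x=2, c_g=2, seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            attention_gate(rng.normal(size=(2, 4, 4)), rng.normal(size=(2, 6, 6)), params)

    def test_nonzero_bias_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            AttentionGateParams(w_x=[[1.0]], w_g=[[1.0]], w_s=[1.0], b_g=0.1)


class TestDwtBands:
    def test_constant_input_reference_values(self):
        c = 3.7
        bands = dwt_bands(np.full((2, 8, 8), c))
        # two orthonormal lowpass stages each scale a constant by sqrt(2)
        assert np.allclose(bands.LL, 2 * c, atol=1e-10)
        for det in (bands.LH, bands.HL, bands.HH):
            assert np.allclose(det, 0.0, atol=1e-10)

    def test_matches_pywavelets_reference(self, rng):
        x = rng.normal(size=(3, 16, 12))
        bands = dwt_bands(x)
        for ch in range(3):
            ca, (ch_det, cv, cd) = pywt.dwt2(x[ch], "db2", mode="periodization")
            assert np.allclose(bands.LL[ch], ca, atol=1e-10)
            assert np.allclose(bands.LH[ch], ch_det, atol=1e-10)
            assert np.allclose(bands.HL[ch], cv, atol=1e-10)
            assert np.allclose(bands.HH[ch], cd, atol=1e-10)

    def test_band_shapes_halve(self, rng):
        bands = dwt_bands(rng.normal(size=(1, 128, 128)))
        assert bands.LL.shape == (1, 64, 64)

    def test_perfect_reconstruction(self, rng):
        x = rng.normal(size=(2, 16, 16))
        assert np.allclose(idwt_bands(dwt_bands(x)), x, atol=1e-6)

    def test_linearity(self, rng):
        x = rng.normal(size=(1, 8, 8))
        y = rng.normal(size=(1, 8, 8))
        a, b = 2.5, -1.25
        lhs = dwt_bands(a * x + b * y)
        bx, by = dwt_bands(x), dwt_bands(y)
        for name in ("LL", "LH", "HL", "HH"):
            assert np.allclose(
                getattr(lhs, name), a * getattr(bx, name) + b * getattr(by, name), atol=1e-6
            )

    def test_energy_conservation(self, rng):
        x = rng.normal(size=(2, 32, 32))
        bands = dwt_bands(x)
        total = sum((getattr(bands, n) ** 2).sum() for n in ("LL", "LH", "HL", "HH"))
        assert total == pytest.approx((x**2).sum(), rel=1e-4)

    def test_odd_dims_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            dwt_bands(rng.normal(size=(1, 7, 8)))


class TestWaveletGate:
    def test_constant_input_zero_detail_channels(self):
        params = AttentionGateParams.init(c_x=2, c_g=1, seed=1)
        x = np.full((2, 8, 8), 1.3)
        g = np.zeros((1, 4, 4))
        out = wavelet_gate(x, g, params)
        assert out.shape == (6, 8, 8)
        assert np.allclose(out[2:], 0.0, atol=1e-10)  # LH and HL streams

    def test_channel_and_shape_bookkeeping(self, rng):
        c = 3
        params = AttentionGateParams.init(c_x=c, c_g=2, seed=0)
        x = rng.normal(size=(c, 128, 128))
        g = rng.normal(size=(2, 64, 64))
        out = wavelet_gate(x, g, params)
        assert out.shape == (3 * c, 128, 128)

    def test_keep_hh_adds_fourth_stream(self, rng):
        params = AttentionGateParams.init(c_x=2, c_g=2, seed=0)
        x = rng.normal(size=(2, 8, 8))
        g = rng.normal(size=(2, 4, 4))
        assert wavelet_gate(x, g, params, keep_hh=True).shape == (8, 8, 8)

    def test_deterministic(self, rng):
        params = AttentionGateParams.init(c_x=2, c_g=2, seed=0)
        x = rng.normal(size=(2, 8, 8))
        g = rng.normal(size=(2, 4, 4))
        assert np.array_equal(wavelet_gate(x, g, params), wavelet_gate(x, g, params))


class TestGateModules:
    """The trainable (autodiff) gates must agree with the functional math."""

    def test_attention_module_matches_functional(self, rng):
        mod = AttentionGateModule(c_x=3, c_g=2, rng=np.random.default_rng(0))
        x = rng.normal(size=(3, 6, 6)).astype(np.float32)
        g = rng.normal(size=(2, 6, 6)).astype(np.float32)
        params = AttentionGateParams(
            w_x=mod.theta_x.w.data[0, 0].T,
            w_g=mod.phi_g.w.data[0, 0].T,
            w_s=mod.psi.w.data[0, 0, :, 0],
        )
        # NHWC module input
        out_mod = mod(Tensor(x.transpose(1, 2, 0)[None]), Tensor(g.transpose(1, 2, 0)[None]))
        out_fn = attention_gate(x, g, params)
        assert np.allclose(out_mod.data[0].transpose(2, 0, 1), out_fn, atol=1e-5)

    def test_wavelet_module_detail_streams_match_dwt(self, rng):
        mod = WaveletGateModule(c_x=2, c_g=1, rng=np.random.default_rng(0))
        x = rng.normal(size=(2, 8, 8)).astype(np.float32)
        g = rng.normal(size=(1, 4, 4)).astype(np.float32)
        out = mod(Tensor(x.transpose(1, 2, 0)[None]), Tensor(g.transpose(1, 2, 0)[None]))
        # learned upsampling: just check shape here; band math is covered above
        assert out.data.shape == (1, 8, 8, 6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_dwt_energy_conservation_property(seed):
    x = np.random.default_rng(seed).normal(size=(1, 16, 16))
    bands = dwt_bands(x)
    total = sum((getattr(bands, n) ** 2).sum() for n in ("LL", "LH", "HL", "HH"))
    assert total == pytest.approx((x**2).sum(), rel=1e-4)
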