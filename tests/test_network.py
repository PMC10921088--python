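import numpy as np
import pytest

from watunet.autograd import Tensor
from watunet.layers import Adam
from watunet.network import (
    NetworkConfig,
    SHARPEN_KERNEL,
    SharpenSkip,
    build_model,
    count_parameters,
)
from watunet.objectives import combined_loss_grad

SMALL = dict(depth=2, base_channels=4, input_size=(32, 32))


def hand_counted_parameters(depth, base, convs=2, mode="plain", cin=1):
    """Independent layer-arithmetic enumeration of trainable parameters."""
    ch = [base * 2**l for l in range(depth + 1)]

    def conv_block(c_in, c_out):
        total = 0
        for i in range(convs):
            ci = c_in if i == 0 else c_out
            total += 9 * ci * c_out + c_out  # conv + bias
            total += 2 * c_out  # batch-norm gamma/beta
        return total

    total = conv_block(cin, ch[0])
    for l in range(1, depth):
        total += conv_block(ch[l - 1], ch[l])
    total += conv_block(ch[depth - 1], ch[depth])  # bottleneck
    for l in range(depth):
        total += 9 * ch[l + 1] * ch[l] + ch[l]  # transposed conv
        if mode == "plain" or mode == "sharpen":
            skip_ch = ch[l]
        elif mode == "attention":
            total += 2 * ch[l] ** 2 + ch[l]  # theta_x, phi_g, psi (no biases)
            skip_ch = ch[l]
        else:  # watunet: wavelet gate (AG + learned upsampler) plus plain AG
            total += ch[l] ** 2 + ch[l + 1] * ch[l] + ch[l]  # AG on LL, gated by below
            total += 9 * (3 * ch[l]) ** 2 + 3 * ch[l]  # transposed-conv upsampler
            total += 2 * ch[l] ** 2 + ch[l]  # AG over x_enc
            skip_ch = 4 * ch[l]
        total += conv_block(ch[l] + skip_ch, ch[l])
    total += ch[0] * 1 + 1  # 1x1 head
    return total


@pytest.mark.parametrize("mode", ["plain", "attention", "sharpen", "watunet"])
def test_parameter_count_matches_layer_arithmetic(mode):
    cfg = NetworkConfig(skip_mode=mode, **SMALL)
    model = build_model(cfg, seed=0)
    assert count_parameters(model) == hand_counted_parameters(2, 4, mode=mode)


@pytest.mark.parametrize("mode", ["plain", "attention", "sharpen", "watunet"])
def test_forward_shape_and_probability_range(mode):
    cfg = NetworkConfig(skip_mode=mode, **SMALL)
    model = build_model(cfg, seed=0).eval()
    x = np.random.default_rng(0).random((2, 32, 32, 1), dtype=np.float32)
    y = model.forward(x).data
    assert y.shape == (2, 32, 32, 1)
    assert np.all((y > 0) & (y < 1))


def test_identical_seeds_give_identical_builds_and_outputs():
    cfg = NetworkConfig(skip_mode="plain", **SMALL)
    a = build_model(cfg, seed=7).eval()
    b = build_model(cfg, seed=7).eval()
    for pa, pb in zip(a.parameters(), b.parameters()):
        assert np.array_equal(pa.data, pb.data)
    x = np.random.default_rng(1).random((3, 32, 32, 1), dtype=np.float32)
    assert np.array_equal(a.forward(x).data, b.forward(x).data)
    c = build_model(cfg, seed=8)
    assert not np.array_equal(a.parameters()[0].data, c.parameters()[0].data)


def test_indivisible_input_rejected_at_build_time():
    with pytest.raises(ValueError, match="divisible"):
        NetworkConfig(depth=4, base_channels=4, skip_mode="watunet", input_size=(48, 48))
    # 48 = 16*3 works for plain at depth 4 but not for watunet (needs /32)
    NetworkConfig(depth=4, base_channels=4, skip_mode="plain", input_size=(48, 48))


def test_unknown_skip_mode_rejected():
    with pytest.raises(ValueError, match="skip_mode"):
        NetworkConfig(skip_mode="resnet", **SMALL)


def test_sharpen_skip_preserves_constant_maps():
    assert SHARPEN_KERNEL.sum() == pytest.approx(1.0)
    skip = SharpenSkip(c=3)
    x = Tensor(np.full((1, 8, 8, 3), 2.5, dtype=np.float32))
    out = skip(x, None, None)
    assert np.allclose(out.data, 2.5, atol=1e-5)


def test_watunet_skip_channel_bookkeeping():
    cfg = NetworkConfig(skip_mode="watunet", **SMALL)
    model = build_model(cfg, seed=0).eval()
    x = Tensor(np.random.default_rng(0).random((1, 32, 32, 4), dtype=np.float32))
    below = Tensor(np.random.default_rng(1).random((1, 16, 16, 8), dtype=np.float32))
    up = Tensor(np.random.default_rng(2).random((1, 32, 32, 4), dtype=np.float32))
    out = model.skip0(x, below, up)
    assert out.data.shape == (1, 32, 32, 16)  # 3C from the wavelet gate + C attention


def test_plain_skip_is_identity():
    cfg = NetworkConfig(skip_mode="plain", **SMALL)
    model = build_model(cfg, seed=0)
    x = Tensor(np.random.default_rng(0).random((1, 32, 32, 4), dtype=np.float32))
    assert model.skip0(x, None, None) is x


@pytest.mark.parametrize("mode", ["plain", "attention", "sharpen", "watunet"])
def test_gradients_reach_first_encoder_block(mode):
    cfg = NetworkConfig(skip_mode=mode, **SMALL)
    model = build_model(cfg, seed=0).train()
    first = model.enc0.conv0.w
    before = first.data.copy()
    opt = Adam(model.parameters())
    rng = np.random.default_rng(0)
    x = rng.random((4, 32, 32, 1), dtype=np.float32)
    y = (rng.random((4, 32, 32)) > 0.8).astype(np.float32)
    out = model.forward(x)
    _, grad = combined_loss_grad(out.data[..., 0], y)
    opt.zero_grad()
    out.backward(grad[..., None])
    opt.step()
    assert not np.array_equal(first.data, before)
    assert np.any(np.abs(first.data - before) > 0)


def test_eval_output_invariant_to_batch_composition():
    cfg = NetworkConfig(skip_mode="watunet", **SMALL)
    model = build_model(cfg, seed=0)
    x = np.random.default_rng(3).random((4, 32, 32), dtype=np.float32)
    full = model.predict(x)
    singles = np.stack([model.predict(x[i : i + 1])[0] for i in range(4)])
    assert np.allclose(full, singles, atol=1e-6)


def test_skip_tensors_spatially_aligned_at_every_level():
    # forward succeeds at every depth only if every skip aligns with the decoder
    for mode in ("plain", "attention", "sharpen", "watunet"):
        cfg = NetworkConfig(depth=3, base_channels=4, skip_mode=mode, input_size=(32, 32))
        model = build_model(cfg, seed=0).eval()
        out = model.forward(np.zeros((1, 32, 32, 1), np.float32))
        assert out.data.shape == (1, 32, 32, 1)
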