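"""Segmentation network assembly: one UNet backbone, four skip-connection modes.

The backbone is a conventional UNet: ``depth`` encoder blocks (stacked
3x3 conv / batch-norm / swish, 2x2 max-pool, dropout), a bottleneck
block, and a mirrored decoder (3x3 stride-2 transposed convolution,
concatenation with the skip tensor, conv block, dropout), closed by a
1x1 convolution and sigmoid.  Channel width doubles per level.

What varies between models is only how the skip tensor is produced:

- ``plain``     the encoder feature, unchanged;
- ``attention`` the encoder feature rescaled by an additive attention
                gate whose gating signal is the decoder's upsampled
                feature at the same resolution;
- ``sharpen``   the encoder feature convolved per channel with the fixed
                3x3 Laplacian-sharpening kernel (sums to 1);
- ``watunet``   concatenation of the wavelet gate (attention-gated LL
                plus LH/HL detail bands, learned 2x upsampling) and an
                attention gate over the raw encoder feature - the two
                streams carry frequency- and saliency-selected
                information side by side into the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import BatchNorm2d, Conv2d, ConvTranspose2d, Dropout, Module
from .gates import AttentionGateModule, WaveletGateModule

SKIP_MODES = ("plain", "attention", "sharpen", "watunet")

# Laplacian sharpening kernel; sums to 1, so flat regions pass through unchanged.
SHARPEN_KERNEL = np.array(
    [[-1.0, -1.0, -1.0], [-1.0, 9.0, -1.0], [-1.0, -1.0, -1.0]], dtype=np.float32
)


@dataclass
class NetworkConfig:
    depth: int = 4
    base_channels: int = 16
    convs_per_block: int = 2
    encoder_dropout: float = 0.1
    decoder_dropout: float = 0.5
    skip_mode: str = "watunet"
    activation: str = "swish"
    input_size: tuple[int, int] = (128, 128)
    keep_hh: bool = False
    wavelet: str = "db2"

    def __post_init__(self):
        if self.skip_mode not in SKIP_MODES:
            raise ValueError(f"unknown skip_mode {self.skip_mode!r}; choose from {SKIP_MODES}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 <= self.encoder_dropout < 1 and 0 <= self.decoder_dropout < 1):
            raise ValueError("dropout rates must lie in [0, 1)")
        h, w = self.input_size
        # watunet needs even dims at the deepest skip (one extra halving for the DWT)
        div = 2 ** (self.depth + 1) if self.skip_mode == "watunet" else 2**self.depth
        if h % div or w % div:
            raise ValueError(
                f"input size {h}x{w} must be divisible by {div} for "
                f"skip_mode={self.skip_mode!r} at depth {self.depth}"
            )

    @property
    def channels(self) -> list[int]:
        """Encoder channel schedule, one entry per level plus the bottleneck."""
        return [self.base_channels * 2**l for l in range(self.depth + 1)]


def _activation(name: str):
    try:
        return {"swish": ag.swish, "relu": ag.relu}[name]
    except KeyError:
        raise ValueError(f"unsupported activation {name!r}") from None


class ConvBlock(Module):
    def __init__(self, cin: int, cout: int, n_convs: int, act: str, rng: np.random.Generator):
        super().__init__()
        self.act = _activation(act)
        self.convs = []
        self.norms = []
        for i in range(n_convs):
            conv = Conv2d(cin if i == 0 else cout, cout, 3, rng)
            norm = BatchNorm2d(cout)
            setattr(self, f"conv{i}", conv)
            setattr(self, f"norm{i}", norm)
            self.convs.append(conv)
            self.norms.append(norm)

    def __call__(self, x: Tensor) -> Tensor:
        for conv, norm in zip(self.convs, self.norms):
            x = self.act(norm(conv(x)))
        return x


class PlainSkip(Module):
    def __call__(self, x_enc: Tensor, below: Tensor, up: Tensor) -> Tensor:
        return x_enc


class SharpenSkip(Module):
    """Fixed per-channel Laplacian sharpening with replicate borders (not trainable)."""

    def __init__(self, c: int):
        super().__init__()
        w = np.zeros((3, 3, c, c), dtype=np.float32)
        for i in range(c):
            w[:, :, i, i] = SHARPEN_KERNEL
        self._w = Tensor(w)  # deliberately not registered: no gradient update

    def __call__(self, x_enc: Tensor, below: Tensor, up: Tensor) -> Tensor:
        return ag.conv2d(ag.replicate_pad1(x_enc), self._w, pad=0)


class AttentionSkip(Module):
    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.gate = AttentionGateModule(c_x=c, c_g=c, rng=rng)

    def __call__(self, x_enc: Tensor, below: Tensor, up: Tensor) -> Tensor:
        return self.gate(x_enc, up)


class WatunetSkip(Module):
    """Parallel wavelet gate + attention gate; output has 4x the skip channels."""

    def __init__(self, c: int, c_below: int, rng: np.random.Generator, wavelet: str, keep_hh: bool):
        super().__init__()
        self.wg = WaveletGateModule(c_x=c, c_g=c_below, rng=rng, wavelet=wavelet, keep_hh=keep_hh)
        self.ag = AttentionGateModule(c_x=c, c_g=c, rng=rng)

    def __call__(self, x_enc: Tensor, below: Tensor, up: Tensor) -> Tensor:
        return ag.concat([self.wg(x_enc, below), self.ag(x_enc, up)], axis=-1)


class SegmentationModel(Module):
    """Encoder-decoder segmentation network emitting a per-pixel probability map."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        ch = config.channels  # level widths; ch[-1] is the bottleneck
        d = config.depth

        for l in range(d):
            cin = 1 if l == 0 else ch[l - 1]
            setattr(self, f"enc{l}", ConvBlock(cin, ch[l], config.convs_per_block, config.activation, rng))
        self.bottleneck = ConvBlock(ch[d - 1], ch[d], config.convs_per_block, config.activation, rng)

        for l in reversed(range(d)):
            c_below = ch[l + 1]
            setattr(self, f"upconv{l}", ConvTranspose2d(c_below, ch[l], rng))
            if config.skip_mode == "plain":
                skip: Module = PlainSkip()
                skip_ch = ch[l]
            elif config.skip_mode == "sharpen":
                skip = SharpenSkip(ch[l])
                skip_ch = ch[l]
            elif config.skip_mode == "attention":
                skip = AttentionSkip(ch[l], rng)
                skip_ch = ch[l]
            else:  # watunet
                skip = WatunetSkip(ch[l], c_below, rng, config.wavelet, config.keep_hh)
                skip_ch = (5 if config.keep_hh else 4) * ch[l]
            setattr(self, f"skip{l}", skip)
            setattr(self, f"dec{l}", ConvBlock(ch[l] + skip_ch, ch[l], config.convs_per_block, config.activation, rng))

        self.head = Conv2d(ch[0], 1, 1, rng)
        self.enc_drop = Dropout(config.encoder_dropout)
        self.dec_drop = Dropout(config.decoder_dropout)
        self._drop_rng = np.random.default_rng(seed + 1)

    def reseed_dropout(self, seed: int) -> None:
        self._drop_rng = np.random.default_rng(seed)

    def forward(self, x) -> Tensor:
        """Run the network; accepts (N,H,W,1) float arrays in [0,1]."""
        t = x if isinstance(x, Tensor) else Tensor(x)
        if t.data.ndim != 4 or t.data.shape[-1] != 1:
            raise ValueError(f"expected (N,H,W,1) input, got {t.data.shape}")
        d = self.config.depth
        skips: list[Tensor] = []
        for l in range(d):
            t = getattr(self, f"enc{l}")(t)
            skips.append(t)
            t = self.enc_drop(ag.maxpool2x2(t), self._drop_rng)
        t = self.enc_drop(self.bottleneck(t), self._drop_rng)
        for l in reversed(range(d)):
            below = t
            up = getattr(self, f"upconv{l}")(below)
            skip = getattr(self, f"skip{l}")(skips[l], below, up)
            t = getattr(self, f"dec{l}")(ag.concat([up, skip], axis=-1))
            t = self.dec_drop(t, self._drop_rng)
        return ag.sigmoid(self.head(t))

    __call__ = forward

    def predict(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Probability maps (N,H,W) for (N,H,W,1) or (N,H,W) input, in evaluation mode."""
        was_training = self.training
        self.eval()
        if images.ndim == 3:
            images = images[..., None]
        outs = []
        for i in range(0, len(images), batch_size):
            outs.append(self.forward(images[i : i + batch_size]).data[..., 0])
        if was_training:
            self.train()
        return np.concatenate(outs, axis=0)


def build_model(config: NetworkConfig, seed: int = 0) -> SegmentationModel:
    """Construct a seeded segmentation model; same config+seed => identical weights."""
    return SegmentationModel(config, seed)


def count_parameters(model: Module) -> int:
    return sum(p.data.size for p in model.parameters())
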