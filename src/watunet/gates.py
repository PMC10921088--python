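"""Skip-connection gates: additive attention and wavelet sub-band routing.

Two views of the same math live here.

*Functional, numpy-only* (:func:`attention_gate`, :func:`dwt_bands`,
:func:`wavelet_gate`): operate on plain ``(C, H, W)`` arrays with
explicit weight containers.  These are the reference surface used by the
test suite and by anyone who wants the gate math without the network.

*Trainable modules* (:class:`AttentionGateModule`,
:class:`WaveletGateModule`): the same operations expressed through the
autodiff tape so they can sit inside the segmentation network.

The attention gate follows the additive formulation: skip features x and
a gating signal g are each projected by a 1x1 convolution, summed, passed
through swish, projected to a single channel, and squashed by a sigmoid
into per-pixel coefficients a in (0,1) that rescale x.  Both biases are
fixed at zero.

The wavelet gate decomposes the skip features with a single-level 2-D
Daubechies-2 DWT in periodization mode (each sub-band exactly half
resolution).  The approximation band LL is attention-gated against a
coarse decoder feature; the horizontal and vertical detail bands LH and
HL are carried through unchanged; the diagonal band HH, dominated by
speckle noise, is discarded by default.  The three streams are
concatenated and upsampled back to the skip resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pywt

from . import autograd as ag
from .autograd import Tensor
from .layers import Conv2d, ConvTranspose2d, Module, he_uniform

__all__ = [
    "swish",
    "AttentionGateParams",
    "attention_gate",
    "WaveletBands",
    "dwt_analysis_matrices",
    "dwt_bands",
    "idwt_bands",
    "wavelet_gate",
    "AttentionGateModule",
    "WaveletGateModule",
]


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(v, -60, 60)))


def swish(v):
    """Elementwise swish activation, v * sigmoid(v)."""
    v = np.asarray(v, dtype=float)
    return v * _sigmoid(v)


# ---------------------------------------------------------------------------
# additive attention gate


@dataclass
class AttentionGateParams:
    """Weights of one additive attention gate.

    ``w_x`` maps the skip channels and ``w_g`` the gating channels to a
    common intermediate width; ``w_s`` collapses the intermediate to the
    single attention channel.  The two biases exist for completeness but
    are fixed at zero.
    """

    w_x: np.ndarray  # (c_int, c_x)
    w_g: np.ndarray  # (c_int, c_g)
    w_s: np.ndarray  # (c_int,)
    b_g: float = 0.0
    b_s: float = 0.0

    def __post_init__(self):
        self.w_x = np.asarray(self.w_x, dtype=float)
        self.w_g = np.asarray(self.w_g, dtype=float)
        self.w_s = np.asarray(self.w_s, dtype=float).reshape(-1)
        if self.w_x.shape[0] != self.w_g.shape[0] or self.w_s.shape[0] != self.w_x.shape[0]:
            raise ValueError(
                "w_x and w_g must project to the same intermediate width as w_s: "
                f"{self.w_x.shape}, {self.w_g.shape}, {self.w_s.shape}"
            )
        if self.b_g != 0.0 or self.b_s != 0.0:
            raise ValueError("gate biases are fixed at zero")

    @classmethod
    def init(cls, c_x: int, c_g: int, c_int: int | None = None, seed: int = 0):
        c_int = c_x if c_int is None else c_int
        rng = np.random.default_rng(seed)
        return cls(
            w_x=he_uniform(rng, (c_int, c_x), c_x),
            w_g=he_uniform(rng, (c_int, c_g), c_g),
            w_s=he_uniform(rng, (c_int,), c_int),
        )


def attention_gate(
    x: np.ndarray,
    g: np.ndarray,
    params: AttentionGateParams,
    return_coefficients: bool = False,
):
    """Gate skip features ``x`` (C,H,W) with gating signal ``g`` (Cg,H,W).

    Computes a = sigmoid(w_s . swish(W_x x + W_g g)) per pixel and returns
    x * a (the coefficients broadcast over channels).
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=float)
    if x.ndim != 3 or g.ndim != 3:
        raise ValueError("attention_gate expects (C, H, W) arrays")
    if x.shape[1:] != g.shape[1:]:
        raise ValueError(f"spatial mismatch between x {x.shape} and g {g.shape}")
    t = np.einsum("oc,chw->ohw", params.w_x, x) + np.einsum("oc,chw->ohw", params.w_g, g)
    a = _sigmoid(np.einsum("c,chw->hw", params.w_s, swish(t)))[None]
    out = x * a
    if return_coefficients:
        return out, a
    return out


# ---------------------------------------------------------------------------
# wavelet decomposition


@dataclass
class WaveletBands:
    """Single-level 2-D DWT sub-bands, each at half the input resolution."""

    LL: np.ndarray
    LH: np.ndarray  # horizontal detail (highpass rows, lowpass cols)
    HL: np.ndarray  # vertical detail (lowpass rows, highpass cols)
    HH: np.ndarray  # diagonal detail


_MATRIX_CACHE: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}


def dwt_analysis_matrices(n: int, wavelet: str = "db2") -> tuple[np.ndarray, np.ndarray]:
    """Lowpass/highpass analysis matrices (n/2, n) for a periodized DWT.

    Row k of the lowpass matrix holds the dec_lo filter wrapped circularly
    so that ``Lo @ x`` equals the approximation half of a periodization-mode
    single-level DWT of a length-n signal.
    """
    if n % 2:
        raise ValueError(f"periodized DWT needs an even length, got {n}")
    key = (n, wavelet)
    if key not in _MATRIX_CACHE:
        w = pywt.Wavelet(wavelet)
        mats = []
        for filt in (w.dec_lo, w.dec_hi):
            L = len(filt)
            off = L // 2
            m = np.zeros((n // 2, n))
            for k in range(n // 2):
                for i, f in enumerate(filt):
                    m[k, (2 * k + off - i) % n] += f
            mats.append(m)
        _MATRIX_CACHE[key] = (mats[0], mats[1])
    return _MATRIX_CACHE[key]


def dwt_bands(x: np.ndarray, wavelet: str = "db2") -> WaveletBands:
    """Per-channel single-level 2-D DWT of a (C, H, W) feature map."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("dwt_bands expects a (C, H, W) array")
    _, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"dwt_bands needs even spatial dims, got {h}x{w}")
    lo_h, hi_h = dwt_analysis_matrices(h, wavelet)
    lo_w, hi_w = dwt_analysis_matrices(w, wavelet)

    def band(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.einsum("ij,cjk,lk->cil", rows, x, cols, optimize=True)

    return WaveletBands(
        LL=band(lo_h, lo_w),
        LH=band(hi_h, lo_w),
        HL=band(lo_h, hi_w),
        HH=band(hi_h, hi_w),
    )


def idwt_bands(bands: WaveletBands, wavelet: str = "db2") -> np.ndarray:
    """Inverse of :func:`dwt_bands`; exact because the transform is orthonormal."""
    _, h2, w2 = bands.LL.shape
    lo_h, hi_h = dwt_analysis_matrices(2 * h2, wavelet)
    lo_w, hi_w = dwt_analysis_matrices(2 * w2, wavelet)

    def lift(b: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.einsum("ji,cjk,kl->cil", rows, b, cols, optimize=True)

    return (
        lift(bands.LL, lo_h, lo_w)
        + lift(bands.LH, hi_h, lo_w)
        + lift(bands.HL, lo_h, hi_w)
        + lift(bands.HH, hi_h, hi_w)
    )


def _nearest_upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=-2), 2, axis=-1)


def wavelet_gate(
    x: np.ndarray,
    g_coarse: np.ndarray,
    params: AttentionGateParams,
    wavelet: str = "db2",
    keep_hh: bool = False,
    upsample: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Wavelet-gated skip tensor for encoder features ``x`` (C,H,W).

    ``g_coarse`` is a decoder-side gating feature already living at the
    half resolution of the sub-bands.  Returns the upsampled concatenation
    of the attention-gated LL band with the LH and HL detail bands (3C
    channels, or 4C when ``keep_hh``); spatial size matches ``x``.  The
    in-network module replaces the default nearest-neighbour upsampling
    with a learned transposed convolution.
    """
    bands = dwt_bands(x, wavelet)
    gated = attention_gate(bands.LL, g_coarse, params)
    streams = [gated, bands.LH, bands.HL]
    if keep_hh:
        streams.append(bands.HH)
    stacked = np.concatenate(streams, axis=0)
    up = _nearest_upsample2 if upsample is None else upsample
    return up(stacked)


# ---------------------------------------------------------------------------
# trainable modules


class AttentionGateModule(Module):
    """Additive attention gate as a trainable network block (biases fixed at 0)."""

    def __init__(self, c_x: int, c_g: int, rng: np.random.Generator, c_int: int | None = None):
        super().__init__()
        c_int = c_x if c_int is None else c_int
        self.theta_x = Conv2d(c_x, c_int, 1, rng, bias=False)
        self.phi_g = Conv2d(c_g, c_int, 1, rng, bias=False)
        self.psi = Conv2d(c_int, 1, 1, rng, bias=False)

    def __call__(self, x: Tensor, g: Tensor) -> Tensor:
        if x.shape[1:3] != g.shape[1:3]:
            raise ValueError(f"spatial mismatch between x {x.shape} and g {g.shape}")
        t = ag.swish(ag.add(self.theta_x(x), self.phi_g(g)))
        a = ag.sigmoid(self.psi(t))
        return ag.mul(x, a)


class WaveletGateModule(Module):
    """Wavelet gate with a learned 2x transposed-convolution upsampler.

    The coarse decoder feature is taken at the sub-band resolution and fed
    straight to the attention gate (its 1x1 projection doubles as the
    channel reconciliation).  Output channels: 3*C, or 4*C with keep_hh.
    """

    def __init__(
        self,
        c_x: int,
        c_g: int,
        rng: np.random.Generator,
        wavelet: str = "db2",
        keep_hh: bool = False,
    ):
        super().__init__()
        self.wavelet = wavelet
        self.keep_hh = keep_hh
        self.gate = AttentionGateModule(c_x, c_g, rng)
        n_streams = 4 if keep_hh else 3
        self.up = ConvTranspose2d(n_streams * c_x, n_streams * c_x, rng)

    def __call__(self, x: Tensor, g_coarse: Tensor) -> Tensor:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"wavelet gate needs even spatial dims, got {h}x{w}")
        lo_h, hi_h = dwt_analysis_matrices(h, self.wavelet)
        lo_w, hi_w = dwt_analysis_matrices(w, self.wavelet)
        lo_h = lo_h.astype(np.float32)
        hi_h = hi_h.astype(np.float32)
        lo_w = lo_w.astype(np.float32)
        hi_w = hi_w.astype(np.float32)
        row_lo = ag.matmul_h(x, lo_h)
        row_hi = ag.matmul_h(x, hi_h)
        ll = ag.matmul_w(row_lo, lo_w)
        lh = ag.matmul_w(row_hi, lo_w)
        hl = ag.matmul_w(row_lo, hi_w)
        streams = [self.gate(ll, g_coarse), lh, hl]
        if self.keep_hh:
            streams.append(ag.matmul_w(row_hi, hi_w))
        return self.up(ag.concat(streams, axis=-1))
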