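"""Building blocks of the hierarchical global-context vision transformer.

Token maps are NHWC tensors (batch, height, width, channels).  Local
attention operates on non-overlapping square windows; global attention reuses
a stage-wide set of query tokens produced by progressively downsampling the
stage input, so that every window attends to the same image-level context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn
from ..nn import Tensor


class ShapeError(ValueError):
    """An input violates a spatial-shape precondition."""


# ---------------------------------------------------------------------------
# window bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class WindowSet:
    """A batch of flattened attention windows plus inversion metadata."""

    values: Tensor          # (batch * num_windows, window**2, channels)
    batch: int
    height: int
    width: int
    window: int

    @property
    def num_windows(self) -> int:
        return (self.height // self.window) * (self.width // self.window)

    @property
    def tokens_per_window(self) -> int:
        return self.window * self.window

    @property
    def channels(self) -> int:
        return self.values.shape[-1]


@dataclass
class GlobalTokenSet:
    """Stage-level query tokens shared by every window of the stage."""

    values: Tensor          # (batch, window**2, channels)

    @property
    def tokens(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> int:
        return self.values.shape[-1]


def window_partition(x: Tensor, window: int) -> WindowSet:
    """Cut a token map into non-overlapping window x window tiles."""
    x = nn.ensure_tensor(x)
    b, h, w, c = x.shape
    if h % window or w % window:
        raise ShapeError(f"window {window} does not divide token grid {h}x{w}")
    nh, nw = h // window, w // window
    t = nn.reshape(x, (b, nh, window, nw, window, c))
    t = nn.transpose(t, (0, 1, 3, 2, 4, 5))
    t = nn.reshape(t, (b * nh * nw, window * window, c))
    return WindowSet(values=t, batch=b, height=h, width=w, window=window)


def window_reverse(ws: WindowSet) -> Tensor:
    """Exact inverse of :func:`window_partition`."""
    b, h, w, win = ws.batch, ws.height, ws.width, ws.window
    nh, nw = h // win, w // win
    c = ws.channels
    t = nn.reshape(ws.values, (b, nh, nw, win, win, c))
    t = nn.transpose(t, (0, 1, 3, 2, 4, 5))
    return nn.reshape(t, (b, h, w, c))


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def _relative_position_index(window: int) -> np.ndarray:
    """Flattened pairwise relative-offset index for a window of side w."""
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]            # (2, w^2, w^2)
    rel = rel + (window - 1)                             # shift to >= 0
    return (rel[0] * (2 * window - 1) + rel[1]).astype(np.int64)


class LocalWindowAttention(nn.Module):
    """Multi-head self-attention inside each window with relative position bias."""

    def __init__(self, dim: int, num_heads: int, window: int,
                 qkv_bias: bool = True, relative_bias: bool = True):
        super().__init__()
        if dim % num_heads:
            raise _head_error(dim, num_heads)
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.scale = self.head_dim ** -0.5
        self.window = window
        self.qkv = nn.Linear(dim, 3 * dim, bias=qkv_bias)
        self.proj = nn.Linear(dim, dim)
        if relative_bias:
            self.rel_bias_table = nn.Parameter(
                nn.trunc_normal(((2 * window - 1) ** 2, num_heads))
            )
            self._rel_index = _relative_position_index(window).reshape(-1)
        else:
            self.rel_bias_table = None
            self._rel_index = None

    def attention_weights(self, ws: WindowSet) -> np.ndarray:
        """Row-stochastic attention matrices (for inspection/tests)."""
        with nn.no_grad():
            _, attn = self._attend(ws.values)
        return attn.numpy()

    def _attend(self, x: Tensor):
        bw, n, c = x.shape
        h, d = self.num_heads, self.head_dim
        qkv = self.qkv(x)                                    # (bw, n, 3c)
        qkv = nn.reshape(qkv, (bw, n, 3, h, d))
        qkv = nn.transpose(qkv, (2, 0, 3, 1, 4))             # (3, bw, h, n, d)
        q = nn.reshape(nn.narrow(qkv, 0, 0, 1), (bw, h, n, d))
        k = nn.reshape(nn.narrow(qkv, 0, 1, 1), (bw, h, n, d))
        v = nn.reshape(nn.narrow(qkv, 0, 2, 1), (bw, h, n, d))
        scores = nn.mul(nn.matmul(q, nn.transpose(k, (0, 1, 3, 2))), self.scale)
        if self.rel_bias_table is not None:
            bias = nn.gather_rows(self.rel_bias_table, self._rel_index)   # (n*n, heads)
            bias = nn.transpose(nn.reshape(bias, (n, n, h)), (2, 0, 1))   # (heads, n, n)
            scores = nn.add(scores, nn.reshape(bias, (1, h, n, n)))
        attn = nn.softmax(scores, axis=-1)
        out = nn.matmul(attn, v)                              # (bw, h, n, d)
        out = nn.reshape(nn.transpose(out, (0, 2, 1, 3)), (bw, n, c))
        return self.proj(out), attn

    def forward(self, ws: WindowSet) -> WindowSet:
        out, _ = self._attend(ws.values)
        return WindowSet(out, ws.batch, ws.height, ws.width, ws.window)


class GlobalQueryAttention(nn.Module):
    """Attention whose queries are the shared stage-level global tokens.

    Keys and values come from each window's tokens; no per-window query
    projection of the local tokens is performed, so two windows with the same
    content receive identical outputs.
    """

    def __init__(self, dim: int, num_heads: int, qkv_bias: bool = True):
        super().__init__()
        if dim % num_heads:
            raise _head_error(dim, num_heads)
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.scale = self.head_dim ** -0.5
        self.q = nn.Linear(dim, dim, bias=qkv_bias)
        self.kv = nn.Linear(dim, 2 * dim, bias=qkv_bias)
        self.proj = nn.Linear(dim, dim)

    def _attend(self, ws_values: Tensor, q_tokens: Tensor, num_windows: int):
        bw, n, c = ws_values.shape
        h, d = self.num_heads, self.head_dim
        b, nq, cq = q_tokens.shape
        if nq != n:
            raise ShapeError(f"global token count {nq} != window token count {n}")
        if cq != c:
            raise ShapeError(f"global token channels {cq} != window channels {c}")
        q = self.q(q_tokens)                                  # (b, n, c)
        q = nn.transpose(nn.reshape(q, (b, n, h, d)), (0, 2, 1, 3))
        q = nn.repeat_batch(q, num_windows)                   # (b*nw, h, n, d)
        kv = self.kv(ws_values)
        kv = nn.transpose(nn.reshape(kv, (bw, n, 2, h, d)), (2, 0, 3, 1, 4))
        k = nn.reshape(nn.narrow(kv, 0, 0, 1), (bw, h, n, d))
        v = nn.reshape(nn.narrow(kv, 0, 1, 1), (bw, h, n, d))
        scores = nn.mul(nn.matmul(q, nn.transpose(k, (0, 1, 3, 2))), self.scale)
        attn = nn.softmax(scores, axis=-1)
        out = nn.matmul(attn, v)
        out = nn.reshape(nn.transpose(out, (0, 2, 1, 3)), (bw, n, c))
        return self.proj(out), attn

    def attention_weights(self, ws: WindowSet, q: GlobalTokenSet) -> np.ndarray:
        with nn.no_grad():
            _, attn = self._attend(ws.values, q.values, ws.num_windows)
        return attn.numpy()

    def forward(self, ws: WindowSet, q: GlobalTokenSet) -> WindowSet:
        out, _ = self._attend(ws.values, q.values, ws.num_windows)
        return WindowSet(out, ws.batch, ws.height, ws.width, ws.window)


def _head_error(dim: int, num_heads: int) -> Exception:
    from .config import ConfigurationError

    return ConfigurationError(f"channel width {dim} not divisible by {num_heads} heads")


# ---------------------------------------------------------------------------
# convolutional blocks
# ---------------------------------------------------------------------------

class SqueezeExcite(nn.Module):
    def __init__(self, dim: int, reduction: int = 4):
        super().__init__()
        hidden = max(dim // reduction, 1)
        self.fc1 = nn.Linear(dim, hidden)
        self.fc2 = nn.Linear(hidden, dim)

    def forward(self, x: Tensor) -> Tensor:
        pooled = nn.mean(x, axis=(1, 2))                      # (b, c)
        gate = nn.sigmoid(self.fc2(nn.gelu(self.fc1(pooled))))
        return nn.mul(x, nn.reshape(gate, (x.shape[0], 1, 1, x.shape[-1])))


class FusedMBConv(nn.Module):
    """Depthwise 3x3 -> squeeze-excitation -> 1x1 projection -> residual."""

    def __init__(self, dim: int, se_reduction: int = 4):
        super().__init__()
        self.dw = nn.DepthwiseConv2d(dim, 3)
        self.se = SqueezeExcite(dim, se_reduction)
        self.proj = nn.Conv2d(dim, dim, 1)

    def forward(self, x: Tensor) -> Tensor:
        y = nn.gelu(self.dw(x))
        y = self.se(y)
        y = self.proj(y)
        return nn.add(x, y)


class DepthwiseSeparableConv(nn.Module):
    """Per-channel spatial convolution followed by a 1x1 channel mixer."""

    def __init__(self, channels: int, kernel: int):
        super().__init__()
        if kernel % 2 == 0:
            from .config import ConfigurationError

            raise ConfigurationError(f"depthwise-separable kernel must be odd, got {kernel}")
        self.depthwise = nn.DepthwiseConv2d(channels, kernel)
        self.pointwise = nn.Conv2d(channels, channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class GlobalQueryGenerator(nn.Module):
    """Produce w^2 global query tokens from a stage input of side S = w * 2^k.

    Each of the k halvings applies a fused inverted-residual block followed by
    2x max pooling; a final fused block refines the w x w map before
    flattening it to tokens.
    """

    def __init__(self, dim: int, stage_side: int, window: int):
        super().__init__()
        ratio = stage_side // window
        if stage_side % window or ratio & (ratio - 1):
            from .config import ConfigurationError

            raise ConfigurationError(
                f"stage side {stage_side} / window {window} must be a power of two"
            )
        self.levels = int(round(np.log2(ratio)))
        self.blocks = nn.ModuleList([FusedMBConv(dim) for _ in range(self.levels)])
        self.final = FusedMBConv(dim)
        self.window = window

    def forward(self, x: Tensor) -> GlobalTokenSet:
        for block in self.blocks:
            x = nn.max_pool_2x2(block(x))
        x = self.final(x)
        b = x.shape[0]
        tokens = nn.reshape(x, (b, self.window * self.window, x.shape[-1]))
        return GlobalTokenSet(tokens)


class MixedScaleFeedForward(nn.Module):
    """Mixed-scale depthwise feedforward core (no residual; callers add it).

    1x1 expansion to ratio*C channels, split into two equal branches filtered
    by depthwise 3x3 and 5x5 convolutions, GELU, concatenation, and a 1x1
    projection back to C channels.
    """

    def __init__(self, dim: int, ratio: float):
        super().__init__()
        hidden = int(round(dim * ratio))
        if hidden % 2:
            from .config import ConfigurationError

            raise ConfigurationError(
                f"expansion width {hidden} is odd and cannot split into two branches"
            )
        self.expand = nn.Conv2d(dim, hidden, 1)
        self.branch3 = nn.DepthwiseConv2d(hidden // 2, 3)
        self.branch5 = nn.DepthwiseConv2d(hidden // 2, 5)
        self.project = nn.Conv2d(hidden, dim, 1)
        self.hidden = hidden

    def forward(self, x: Tensor) -> Tensor:
        y = nn.gelu(self.expand(x))
        half = self.hidden // 2
        a = nn.gelu(self.branch3(nn.narrow(y, -1, 0, half)))
        b = nn.gelu(self.branch5(nn.narrow(y, -1, half, half)))
        return self.project(nn.concat([a, b], axis=-1))


def dsc_msfn(x: Tensor, msfn: MixedScaleFeedForward) -> Tensor:
    """Mixed-scale feedforward with its residual connection (shape-preserving)."""
    return nn.add(x, msfn(x))


class Downsample(nn.Module):
    """Halve the token grid and double the channels between stages."""

    def __init__(self, dim: int):
        super().__init__()
        self.norm = nn.LayerNorm(dim)
        self.fmb = FusedMBConv(dim)
        self.reduce = nn.Conv2d(dim, 2 * dim, 3, stride=2)

    def forward(self, x: Tensor) -> Tensor:
        _, h, w, _ = x.shape
        if h % 2 or w % 2:
            raise ShapeError(f"downsample requires even sides, got {h}x{w}")
        return self.reduce(self.fmb(self.norm(x)))


class Stem(nn.Module):
    """Overlapping patch embedding: two 3x3 stride-2 same-padded convolutions."""

    def __init__(self, in_channels: int, dim: int):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, dim, 3, stride=2)
        self.conv2 = nn.Conv2d(dim, dim, 3, stride=2)
        self.norm = nn.LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        _, h, w, _ = x.shape
        if h % 4 or w % 4:
            raise ShapeError(f"stem requires sides divisible by 4, got {h}x{w}")
        return self.norm(self.conv2(nn.gelu(self.conv1(x))))
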