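"""Reusable building blocks for the lightweight leaf-disease classifiers.

Two blocks recur in every model: a convolutional block (two unpadded 3x3
convolutions, leaky ReLU after the second, 2x2 max pooling) and a transformer
block (layer-norm -> multi-head attention -> residual, layer-norm -> gelu MLP
-> residual).  Images enter the transformer path through a patch embedding:
non-overlapping square patches are flattened, linearly projected to a fixed
token dimension and offset by a learned positional vector per position.

All tensors are numpy arrays in height x width x channel layout with a leading
batch axis; token sequences are batch x n_tokens x dim.  Every layer carries
its own parameters and implements `forward` / `backward` so the models can be
trained without an external autodiff framework.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = [
    "glorot_uniform",
    "ConvBlockConfig",
    "TransformerBlockConfig",
    "PatchEmbedConfig",
    "Layer",
    "Conv2D",
    "LeakyReLU",
    "MaxPool2D",
    "Dense",
    "GELU",
    "LayerNorm",
    "Dropout",
    "MultiHeadAttention",
    "PatchExtract",
    "PatchEmbed",
    "TokensToGrid",
    "GlobalAveragePool",
    "Flatten",
    "ConvBlock",
    "TransformerBlock",
    "extract_patches",
    "tokens_to_grid",
    "conv_block_apply",
    "transformer_block_apply",
    "grid_to_tokens",
    "truncated_normal",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvBlockConfig:
    """Hyperparameters of the convolutional block.

    ``filters`` is the channel width of both convolutions.  ``kernel_side``
    and ``pool_side`` are fixed at 3 and 2 for faithful builds; both
    convolutions are valid (no padding) and only the second is followed by a
    leaky ReLU with negative slope ``leaky_slope``.
    """

    filters: int = 16
    kernel_side: int = 3
    pool_side: int = 2
    leaky_slope: float = 0.3

    def __post_init__(self) -> None:
        if self.filters < 1:
            raise ValueError("filters must be >= 1")
        if self.kernel_side < 1 or self.pool_side < 1:
            raise ValueError("kernel_side and pool_side must be >= 1")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must lie in (0, 1)")


@dataclass(frozen=True)
class TransformerBlockConfig:
    """Hyperparameters of the transformer block.

    Four heads on a 64-dimensional token stream, with a two-layer gelu MLP of
    widths (128, 64).  The last MLP width must equal ``proj_dim`` so the
    second residual addition is well formed, and ``proj_dim`` must divide
    evenly into the heads.
    """

    num_heads: int = 4
    proj_dim: int = 64
    mlp_widths: tuple[int, int] = (128, 64)
    mlp_activation: str = "gelu"
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.proj_dim % self.num_heads != 0:
            raise ValueError("proj_dim must be divisible by num_heads")
        if len(self.mlp_widths) != 2:
            raise ValueError("mlp_widths must have exactly two entries")
        if self.mlp_widths[-1] != self.proj_dim:
            raise ValueError(
                "last MLP width must equal proj_dim (residual addition)"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class PatchEmbedConfig:
    """Patch tokenizer: square ``patch_side`` patches projected to
    ``proj_dim`` with a learned positional offset per token position."""

    patch_side: int = 7
    proj_dim: int = 64
    positional: bool = True

    def __post_init__(self) -> None:
        if self.patch_side < 1:
            raise ValueError("patch_side must be >= 1")


def truncated_normal(rng: np.random.Generator, shape, std: float = 0.02
                     ) -> np.ndarray:
    """Normal(0, std) samples re-drawn until within two standard deviations.

    Used for the attention and patch-embedding projections (the usual
    vision-transformer convention)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2.0 * std
    while np.any(bad):
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2.0 * std
    return out


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int,
                   fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform init, the standard for conv and dense layers."""
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# Layer base
# ---------------------------------------------------------------------------

class Layer:
    """A parameterised, differentiable computation step.

    ``params`` and ``grads`` are parallel dicts of numpy arrays.  ``forward``
    caches whatever ``backward`` needs; ``backward`` consumes the gradient of
    the loss w.r.t. the layer output and returns it w.r.t. the input while
    accumulating into ``grads``.
    """

    kind = "layer"

    def __init__(self, name: str | None = None):
        self.name = name if name is not None else type(self).__name__
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        """Per-sample output shape given the per-sample input shape."""
        raise NotImplementedError

    def __call__(self, x, **kw):
        return self.forward(x, **kw)

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    # weight-decay convention: only matrix-valued weights decay
    decay_params: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Convolutional path
# ---------------------------------------------------------------------------

class Conv2D(Layer):
    """Valid (unpadded) 2D convolution, stride 1, no activation."""

    kind = "conv"
    decay_params = ("w",)

    def __init__(self, c_in: int, c_out: int, kernel_side: int, name: str,
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_side
        rng = rng or np.random.default_rng(0)
        k2 = kernel_side * kernel_side
        self.params["w"] = glorot_uniform(
            rng, (kernel_side, kernel_side, c_in, c_out),
            fan_in=k2 * c_in, fan_out=k2 * c_out)
        self.params["b"] = np.zeros(c_out)

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if h < self.k or w < self.k:
            raise ValueError(
                f"layer {self.name!r}: spatial dims {h}x{w} too small for a "
                f"valid {self.k}x{self.k} convolution"
            )
        if c != self.c_in:
            raise ValueError(
                f"layer {self.name!r}: expected {self.c_in} channels, got {c}"
            )
        return (h - self.k + 1, w - self.k + 1, self.c_out)

    def forward(self, x, *, train=False, rng=None):
        oh, ow, _ = self.out_shape(x.shape[1:])
        w, b = self.params["w"], self.params["b"]
        out = np.zeros((x.shape[0], oh, ow, self.c_out), dtype=x.dtype)
        # valid conv as k*k shifted matmuls; cheap for k = 3
        for di in range(self.k):
            for dj in range(self.k):
                out += x[:, di:di + oh, dj:dj + ow, :] @ w[di, dj]
        out += b
        self._x = x
        return out

    def backward(self, dout):
        x, w = self._x, self.params["w"]
        oh, ow = dout.shape[1], dout.shape[2]
        dx = np.zeros_like(x)
        dw = np.zeros_like(w)
        for di in range(self.k):
            for dj in range(self.k):
                patch = x[:, di:di + oh, dj:dj + ow, :]
                dw[di, dj] = np.einsum("bhwc,bhwf->cf", patch, dout)
                dx[:, di:di + oh, dj:dj + ow, :] += dout @ w[di, dj].T
        self.grads["w"] = self.grads.get("w", 0) + dw
        self.grads["b"] = self.grads.get("b", 0) + dout.sum(axis=(0, 1, 2))
        return dx


class LeakyReLU(Layer):
    kind = "activation"

    def __init__(self, slope: float = 0.3, name: str = "leaky_relu"):
        super().__init__(name)
        self.slope = slope

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, *, train=False, rng=None):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class GELU(Layer):
    """Exact Gaussian error linear unit, x * Phi(x)."""

    kind = "activation"

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        return x * self._cdf

    def backward(self, dout):
        x = self._x
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return dout * (self._cdf + x * pdf)


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    window are dropped (floor semantics)."""

    kind = "pool"

    def __init__(self, pool_side: int = 2, name: str = "max_pool"):
        super().__init__(name)
        self.p = pool_side

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if h < self.p or w < self.p:
            raise ValueError(
                f"layer {self.name!r}: spatial dims {h}x{w} too small for "
                f"{self.p}x{self.p} pooling"
            )
        return (h // self.p, w // self.p, c)

    def forward(self, x, *, train=False, rng=None):
        b = x.shape[0]
        oh, ow, c = self.out_shape(x.shape[1:])
        p = self.p
        xc = x[:, :oh * p, :ow * p, :]
        win = xc.reshape(b, oh, p, ow, p, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(b, oh, ow, c, p * p)
        self._arg = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dout):
        b, oh, ow, c = dout.shape
        p = self.p
        dwin = np.zeros((b, oh, ow, c, p * p), dtype=dout.dtype)
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dxc = dwin.reshape(b, oh, ow, c, p, p).transpose(0, 1, 4, 2, 5, 3)
        dx[:, :oh * p, :ow * p, :] = dxc.reshape(b, oh * p, ow * p, c)
        return dx


# ---------------------------------------------------------------------------
# Dense / normalisation / regularisation
# ---------------------------------------------------------------------------

class Dense(Layer):
    """Affine map on the trailing axis; broadcasts over any leading axes."""

    kind = "dense"
    decay_params = ("w",)

    def __init__(self, d_in: int, d_out: int, name: str,
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        self.d_in, self.d_out = d_in, d_out
        rng = rng or np.random.default_rng(0)
        self.params["w"] = glorot_uniform(rng, (d_in, d_out),
                                          fan_in=d_in, fan_out=d_out)
        self.params["b"] = np.zeros(d_out)

    def out_shape(self, in_shape):
        if in_shape[-1] != self.d_in:
            raise ValueError(
                f"layer {self.name!r}: expected trailing dim {self.d_in}, "
                f"got {in_shape[-1]}"
            )
        return in_shape[:-1] + (self.d_out,)

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        x2 = self._x.reshape(-1, self.d_in)
        g2 = dout.reshape(-1, self.d_out)
        self.grads["w"] = self.grads.get("w", 0) + x2.T @ g2
        self.grads["b"] = self.grads.get("b", 0) + g2.sum(axis=0)
        return dout @ self.params["w"].T


class LayerNorm(Layer):
    """Normalisation over the trailing axis with learned scale and shift."""

    kind = "layer_norm"

    def __init__(self, dim: int, eps: float = 1e-6, name: str = "layer_norm"):
        super().__init__(name)
        self.dim, self.eps = dim, eps
        self.params["gamma"] = np.ones(dim)
        self.params["beta"] = np.zeros(dim)

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, *, train=False, rng=None):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, dout):
        g = self.params["gamma"]
        xhat, inv = self._xhat, self._inv
        axes = tuple(range(dout.ndim - 1))
        self.grads["gamma"] = (self.grads.get("gamma", 0)
                               + (dout * xhat).sum(axis=axes))
        self.grads["beta"] = self.grads.get("beta", 0) + dout.sum(axis=axes)
        dxhat = dout * g
        m = self.dim
        return inv / m * (m * dxhat
                          - dxhat.sum(axis=-1, keepdims=True)
                          - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True))


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    kind = "dropout"

    def __init__(self, rate: float, name: str = "dropout"):
        super().__init__(name)
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


# ---------------------------------------------------------------------------
# Attention and tokenisation
# ---------------------------------------------------------------------------

class MultiHeadAttention(Layer):
    """Scaled dot-product attention with ``num_heads`` parallel heads.

    Queries, keys and values are linear maps of the tokens; each head attends
    with scale 1/sqrt(head_dim); head outputs are concatenated and passed
    through an output projection.  The last forward's attention weights are
    kept on ``last_attention`` (batch x heads x queries x keys) for
    inspection.
    """

    kind = "attention"
    decay_params = ("wq", "wk", "wv", "wo")

    def __init__(self, dim: int, num_heads: int, name: str = "attention",
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        if dim % num_heads != 0:
            raise ValueError("dim must be divisible by num_heads")
        self.dim, self.h = dim, num_heads
        self.dh = dim // num_heads
        rng = rng or np.random.default_rng(0)
        for nm in ("wq", "wk", "wv", "wo"):
            self.params[nm] = truncated_normal(rng, (dim, dim))
            self.params["b" + nm[1]] = np.zeros(dim)
        self.last_attention: np.ndarray | None = None

    def out_shape(self, in_shape):
        if in_shape[-1] != self.dim:
            raise ValueError(
                f"layer {self.name!r}: token dim {in_shape[-1]} != {self.dim}"
            )
        return in_shape

    def _split(self, x):
        b, n, _ = x.shape
        return x.reshape(b, n, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):
        b, h, n, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, n, h * dh)

    def forward(self, x, *, train=False, rng=None):
        p = self.params
        q = self._split(x @ p["wq"] + p["bq"])
        k = self._split(x @ p["wk"] + p["bk"])
        v = self._split(x @ p["wv"] + p["bv"])
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(self.dh)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        a = e / e.sum(axis=-1, keepdims=True)
        ctx = self._merge(a @ v)
        self._cache = (x, q, k, v, a, ctx)
        self.last_attention = a
        return ctx @ p["wo"] + p["bo"]

    def backward(self, dout):
        x, q, k, v, a, ctx = self._cache
        p = self.params
        b, n, d = x.shape
        g2 = dout.reshape(-1, d)
        self.grads["wo"] = (self.grads.get("wo", 0)
                            + ctx.reshape(-1, d).T @ g2)
        self.grads["bo"] = self.grads.get("bo", 0) + g2.sum(axis=0)
        dctx = self._split(dout @ p["wo"].T)
        da = dctx @ v.transpose(0, 1, 3, 2)
        dv = a.transpose(0, 1, 3, 2) @ dctx
        # softmax jacobian applied row-wise
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        ds /= math.sqrt(self.dh)
        dq = self._merge(ds @ k)
        dk = self._merge(ds.transpose(0, 1, 3, 2) @ q)
        dv = self._merge(dv)
        x2 = x.reshape(-1, d)
        dx = np.zeros_like(x)
        for nm, g in (("wq", dq), ("wk", dk), ("wv", dv)):
            g2 = g.reshape(-1, d)
            self.grads[nm] = self.grads.get(nm, 0) + x2.T @ g2
            bn = "b" + nm[1]
            self.grads[bn] = self.grads.get(bn, 0) + g2.sum(axis=0)
            dx += g @ p[nm].T
        return dx


class PatchExtract(Layer):
    """Cuts an image (or feature map) into non-overlapping square patches and
    flattens each to a vector, row-major.  Margin pixels beyond the largest
    tiled square are dropped."""

    kind = "patch_extract"

    def __init__(self, patch_side: int, name: str = "patch_extract"):
        super().__init__(name)
        self.p = patch_side

    def grid_side(self, side: int) -> int:
        if side < self.p:
            raise ValueError(
                f"layer {self.name!r}: image side {side} smaller than patch "
                f"side {self.p}"
            )
        return side // self.p

    def out_shape(self, in_shape):
        h, w, c = in_shape
        g = min(self.grid_side(h), self.grid_side(w))
        return (g * g, self.p * self.p * c)

    def forward(self, x, *, train=False, rng=None):
        b, h, w, c = x.shape
        g = min(self.grid_side(h), self.grid_side(w))
        p = self.p
        self._in_shape, self._g = x.shape, g
        xc = x[:, :g * p, :g * p, :]
        pat = xc.reshape(b, g, p, g, p, c).transpose(0, 1, 3, 2, 4, 5)
        return pat.reshape(b, g * g, p * p * c)

    def backward(self, dout):
        b, h, w, c = self._in_shape
        g, p = self._g, self.p
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        pat = dout.reshape(b, g, g, p, p, c).transpose(0, 1, 3, 2, 4, 5)
        dx[:, :g * p, :g * p, :] = pat.reshape(b, g * p, g * p, c)
        return dx


class PatchEmbed(Layer):
    """Linear projection of flat patches plus a learned positional vector."""

    kind = "patch_embed"
    decay_params = ("w",)

    def __init__(self, patch_len: int, n_tokens: int, dim: int,
                 positional: bool = True, name: str = "patch_embed",
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        self.patch_len, self.n_tokens, self.dim = patch_len, n_tokens, dim
        self.positional = positional
        rng = rng or np.random.default_rng(0)
        self.params["w"] = truncated_normal(rng, (patch_len, dim))
        self.params["b"] = np.zeros(dim)
        if positional:
            self.params["pos"] = np.zeros((n_tokens, dim))

    def out_shape(self, in_shape):
        n, plen = in_shape
        if plen != self.patch_len:
            raise ValueError(
                f"layer {self.name!r}: patch length {plen} != {self.patch_len}"
            )
        if n != self.n_tokens:
            raise ValueError(
                f"layer {self.name!r}: token count {n} != {self.n_tokens}"
            )
        return (n, self.dim)

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        out = x @ self.params["w"] + self.params["b"]
        if self.positional:
            out = out + self.params["pos"]
        return out

    def backward(self, dout):
        x2 = self._x.reshape(-1, self.patch_len)
        g2 = dout.reshape(-1, self.dim)
        self.grads["w"] = self.grads.get("w", 0) + x2.T @ g2
        self.grads["b"] = self.grads.get("b", 0) + g2.sum(axis=0)
        if self.positional:
            self.grads["pos"] = self.grads.get("pos", 0) + dout.sum(axis=0)
        return dout @ self.params["w"].T


class TokensToGrid(Layer):
    """Reshapes a token sequence of square length g^2 to a g x g x dim map,
    row-major, inverting the patch-extraction ordering."""

    kind = "tokens_to_grid"

    def out_shape(self, in_shape):
        n, d = in_shape
        g = math.isqrt(n)
        if g * g != n:
            raise ValueError(
                f"layer {self.name!r}: token count {n} is not a perfect square"
            )
        return (g, g, d)

    def forward(self, x, *, train=False, rng=None):
        b, n, d = x.shape
        g, _, _ = self.out_shape((n, d))
        self._n = n
        return x.reshape(b, g, g, d)

    def backward(self, dout):
        b = dout.shape[0]
        return dout.reshape(b, self._n, dout.shape[-1])


class GlobalAveragePool(Layer):
    """Mean over spatial positions (maps) or token positions (sequences)."""

    kind = "pool"

    def out_shape(self, in_shape):
        return (in_shape[-1],)

    def forward(self, x, *, train=False, rng=None):
        self._in_shape = x.shape
        axes = tuple(range(1, x.ndim - 1))
        self._n = int(np.prod([x.shape[a] for a in axes]))
        return x.mean(axis=axes)

    def backward(self, dout):
        shape = (dout.shape[0],) + (1,) * (len(self._in_shape) - 2) \
            + (dout.shape[-1],)
        return np.broadcast_to(dout.reshape(shape) / self._n,
                               self._in_shape).copy()


class Flatten(Layer):
    kind = "reshape"

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, *, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


# ---------------------------------------------------------------------------
# Composite blocks
# ---------------------------------------------------------------------------

class ConvBlock(Layer):
    """Block I: conv 3x3 -> conv 3x3 (both unpadded, linear) -> leaky ReLU
    -> 2x2 max pool.  Input side must be at least 6 so both valid
    convolutions and the pool are feasible; output side is
    floor((side - 4) / 2)."""

    kind = "conv_block"

    def __init__(self, c_in: int, cfg: ConvBlockConfig, name: str = "conv_block",
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        self.cfg = cfg
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2D(c_in, cfg.filters, cfg.kernel_side,
                            f"{name}.conv1", rng)
        self.conv2 = Conv2D(cfg.filters, cfg.filters, cfg.kernel_side,
                            f"{name}.conv2", rng)
        self.act = LeakyReLU(cfg.leaky_slope, f"{name}.leaky_relu")
        self.pool = MaxPool2D(cfg.pool_side, f"{name}.max_pool")

    @property
    def sublayers(self):
        return (self.conv1, self.conv2, self.act, self.pool)

    def out_shape(self, in_shape):
        s = in_shape
        for lyr in self.sublayers:
            s = lyr.out_shape(s)
        return s

    def forward(self, x, *, train=False, rng=None):
        for lyr in self.sublayers:
            x = lyr.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for lyr in reversed(self.sublayers):
            dout = lyr.backward(dout)
        return dout


class TransformerBlock(Layer):
    """Block II: pre-norm attention and MLP branches, each wrapped in a
    residual addition.

    Order: layer-norm -> multi-head attention -> dropout -> add input;
    layer-norm -> dense(w1) -> gelu -> dropout -> dense(w2) -> gelu ->
    dropout -> add.  With zeroed attention and MLP weights both branches
    vanish and the block is the identity map.
    """

    kind = "transformer_block"

    def __init__(self, cfg: TransformerBlockConfig, name: str = "transformer",
                 rng: np.random.Generator | None = None):
        super().__init__(name)
        self.cfg = cfg
        d = cfg.proj_dim
        rng = rng or np.random.default_rng(0)
        self.ln1 = LayerNorm(d, name=f"{name}.ln1")
        self.attn = MultiHeadAttention(d, cfg.num_heads, f"{name}.attn", rng)
        self.drop_attn = Dropout(cfg.dropout, f"{name}.drop_attn")
        self.ln2 = LayerNorm(d, name=f"{name}.ln2")
        w1, w2 = cfg.mlp_widths
        self.fc1 = Dense(d, w1, f"{name}.mlp1", rng)
        self.act1 = GELU(f"{name}.gelu1")
        self.drop1 = Dropout(cfg.dropout, f"{name}.drop1")
        self.fc2 = Dense(w1, w2, f"{name}.mlp2", rng)
        self.act2 = GELU(f"{name}.gelu2")
        self.drop2 = Dropout(cfg.dropout, f"{name}.drop2")

    @property
    def sublayers(self):
        return (self.ln1, self.attn, self.drop_attn, self.ln2, self.fc1,
                self.act1, self.drop1, self.fc2, self.act2, self.drop2)

    def out_shape(self, in_shape):
        if in_shape[-1] != self.cfg.proj_dim:
            raise ValueError(
                f"layer {self.name!r}: token dim {in_shape[-1]} != "
                f"{self.cfg.proj_dim}"
            )
        return in_shape

    def forward(self, x, *, train=False, rng=None):
        a = self.ln1.forward(x, train=train, rng=rng)
        a = self.attn.forward(a, train=train, rng=rng)
        a = self.drop_attn.forward(a, train=train, rng=rng)
        h = x + a
        m = self.ln2.forward(h, train=train, rng=rng)
        for lyr in (self.fc1, self.act1, self.drop1,
                    self.fc2, self.act2, self.drop2):
            m = lyr.forward(m, train=train, rng=rng)
        return h + m

    def backward(self, dout):
        dm = dout
        for lyr in (self.drop2, self.act2, self.fc2,
                    self.drop1, self.act1, self.fc1):
            dm = lyr.backward(dm)
        dh = dout + self.ln2.backward(dm)
        da = self.drop_attn.backward(dh)
        da = self.attn.backward(da)
        return dh + self.ln1.backward(da)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def _batched(x: np.ndarray) -> tuple[np.ndarray, bool]:
    if x.ndim == 3 or x.ndim == 2:  # single map or single token sequence
        return x[None], True
    return x, False


def extract_patches(image: np.ndarray, cfg: PatchEmbedConfig) -> np.ndarray:
    """Tile the top-left square of the image into flat patch vectors.

    Accepts a single ``H x W x C`` map or a batch; returns ``g^2`` vectors of
    length ``patch_side^2 * C`` per image, where ``g = floor(side /
    patch_side)``.
    """
    x, single = _batched(image)
    out = PatchExtract(cfg.patch_side).forward(x)
    return out[0] if single else out


def conv_block_apply(x: np.ndarray, block: ConvBlock) -> np.ndarray:
    """Run an initialised convolutional block in inference mode."""
    xb, single = _batched(x)
    out = block.forward(xb)
    return out[0] if single else out


def transformer_block_apply(tokens: np.ndarray,
                            block: TransformerBlock) -> np.ndarray:
    """Run an initialised transformer block in inference mode."""
    xb, single = _batched(tokens)
    out = block.forward(xb)
    return out[0] if single else out


def grid_to_tokens(x: np.ndarray, embed_cfg: PatchEmbedConfig,
                   embed: PatchEmbed) -> np.ndarray:
    """Patchify a feature map and embed the patches into tokens (the bridge
    from a convolutional block into a transformer block)."""
    xb, single = _batched(x)
    pat = PatchExtract(embed_cfg.patch_side).forward(xb)
    out = embed.forward(pat)
    return out[0] if single else out


def tokens_to_grid(tokens: np.ndarray) -> np.ndarray:
    """Reshape a square-length token sequence back to a spatial map (the
    bridge from a transformer block into a convolutional block)."""
    xb, single = _batched(tokens)
    out = TokensToGrid("tokens_to_grid").forward(xb)
    return out[0] if single else out
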