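"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, gelu, pad, softmax

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "GroupNorm",
    "MultiheadSelfAttention",
    "TransformerBlock",
    "Conv2d",
    "Conv3d",
]


class Module:
    """Base class: parameter discovery, state dicts, grad clearing."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, init_std: float = 0.02):
        self.weight = Tensor(rng.normal(0.0, init_std, size=(in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class GroupNorm(Module):
    """Normalize over channel groups + all trailing spatial axes.

    Input layout: (B, C, *spatial).
    """

    def __init__(self, num_groups: int, channels: int, eps: float = 1e-5):
        if channels % num_groups != 0:
            raise ValueError(f"channels {channels} not divisible by groups {num_groups}")
        self.num_groups = num_groups
        self.channels = channels
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        g = self.num_groups
        xg = x.reshape(b, g, -1)
        mu = xg.mean(axis=-1, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = xc * ((var + self.eps) ** -0.5)
        y = y.reshape((b, c) + spatial)
        shape = (1, c) + (1,) * len(spatial)
        return y * self.gamma.reshape(shape) + self.beta.reshape(shape)


class MultiheadSelfAttention(Module):
    def __init__(self, d_model: int, num_heads: int, rng: np.random.Generator):
        if d_model % num_heads != 0:
            raise ValueError(f"d_model {d_model} not divisible by heads {num_heads}")
        self.d_model = d_model
        self.num_heads = num_heads
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.proj = Linear(d_model, d_model, rng)
        self.last_attention: np.ndarray | None = None  # (B, L, L), head-averaged

    def forward(self, x: Tensor, store_attention: bool = False) -> Tensor:
        b, L, d = x.shape
        h = self.num_heads
        dh = d // h
        qkv = self.qkv(x).reshape(b, L, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (B, h, L, dh)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)
        attn = softmax(scores, axis=-1)
        if store_attention:
            self.last_attention = attn.data.mean(axis=1).copy()
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, L, d)
        return self.proj(out)


class _MLP(Module):
    def __init__(self, d_model: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, hidden, rng)
        self.fc2 = Linear(hidden, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class TransformerBlock(Module):
    """Pre-norm block: x + attn(ln(x)); x + mlp(ln(x))."""

    def __init__(self, d_model: int, num_heads: int, mlp_ratio: float, rng: np.random.Generator):
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiheadSelfAttention(d_model, num_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.mlp = _MLP(d_model, int(d_model * mlp_ratio), rng)

    def forward(self, x: Tensor, store_attention: bool = False) -> Tensor:
        x = x + self.attn(self.ln1(x), store_attention=store_attention)
        return x + self.mlp(self.ln2(x))


def _sliding_cols(x: np.ndarray, kernel: tuple[int, ...]) -> np.ndarray:
    """(B, C, *spatial) -> (B, *out_spatial, C*prod(kernel)) stride-1 windows."""
    nsp = len(kernel)
    axes = tuple(range(2, 2 + nsp))
    win = np.lib.stride_tricks.sliding_window_view(x, kernel, axis=axes)
    # (B, C, *out, *kernel) -> (B, *out, C, *kernel)
    order = (0,) + tuple(range(2, 2 + nsp)) + (1,) + tuple(range(2 + nsp, 2 + 2 * nsp))
    win = np.ascontiguousarray(win.transpose(order))
    out_spatial = win.shape[1:1 + nsp]
    return win.reshape((x.shape[0],) + out_spatial + (-1,))


def _corr_nd(x: Tensor, weight: Tensor, kernel: tuple[int, ...]) -> Tensor:
    """Fused stride-1 valid correlation; x is (B, C, *spatial), weight (O, C, *kernel).

    Forward and both gradients use sliding windows + matmul (no scatter-add),
    which keeps the res-block convolutions fast.
    """
    from .tensor import _make  # local import to avoid a cycle at module load

    nsp = len(kernel)
    o = weight.shape[0]
    c = x.shape[1]
    cols = _sliding_cols(x.data, kernel)          # (B, *out, C*K)
    w2 = weight.data.reshape(o, -1).T             # (C*K, O)
    out = cols @ w2                               # (B, *out, O)
    # -> (B, O, *out)
    fwd_order = (0, 1 + nsp) + tuple(range(1, 1 + nsp))
    result = _make(np.ascontiguousarray(out.transpose(fwd_order)), (x, weight))

    def bw(g):
        # g: (B, O, *out) -> (B, *out, O)
        back_order = (0,) + tuple(range(2, 2 + nsp)) + (1,)
        g_ch_last = np.ascontiguousarray(g.transpose(back_order))
        if weight.requires_grad:
            gw2 = cols.reshape(-1, cols.shape[-1]).T @ g_ch_last.reshape(-1, o)
            weight._accumulate(gw2.T.reshape(weight.shape))
        if x.requires_grad:
            flip = weight.data[(slice(None), slice(None)) + (slice(None, None, -1),) * nsp]
            # M[(o, *k), c] so that gx = windows(g) @ M
            m = flip.transpose((0,) + tuple(range(2, 2 + nsp)) + (1,)).reshape(-1, c)
            widths = ((0, 0), (0, 0)) + tuple((k - 1, k - 1) for k in kernel)
            gpad = np.pad(g, widths)
            gcols = _sliding_cols(gpad, kernel)   # (B, *spatial, O*K)
            gx = gcols @ m                        # (B, *spatial, C)
            gx_order = (0, 1 + nsp) + tuple(range(1, 1 + nsp))
            x._accumulate(np.ascontiguousarray(gx.transpose(gx_order)))

    result._backward = bw
    return result


class _ConvNd(Module):
    """Convolution supporting exactly the two cases used in this package:

    - stride 1 with symmetric zero padding (res-block 3x3 / 3x3x3 kernels);
    - kernel == stride with no padding (non-overlapping learnable pooling).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: tuple[int, ...],
                 rng: np.random.Generator, stride: tuple[int, ...],
                 padding: tuple[int, ...]):
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.patch_mode = stride == kernel and all(p == 0 for p in padding)
        if not self.patch_mode and any(s != 1 for s in stride):
            raise ValueError("only stride 1 or kernel == stride convolutions supported")
        fan_in = in_channels * int(np.prod(kernel))
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(out_channels, in_channels) + kernel),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        nsp = len(self.kernel)
        o = self.weight.shape[0]
        bias_shape = (1, o) + (1,) * nsp
        if self.patch_mode:
            b, c = x.shape[0], x.shape[1]
            spatial = x.shape[2:]
            out_spatial = tuple(s // k for s, k in zip(spatial, self.kernel))
            # split every spatial axis into (blocks, within-block)
            split = []
            for os_, k in zip(out_spatial, self.kernel):
                split.extend([os_, k])
            xr = x.reshape((b, c) + tuple(split))
            block_axes = tuple(2 + 2 * i for i in range(nsp))
            within_axes = tuple(3 + 2 * i for i in range(nsp))
            order = (0,) + block_axes + (1,) + within_axes
            cols = xr.transpose(order).reshape((b,) + out_spatial + (-1,))
            w2 = self.weight.reshape(o, -1).transpose(1, 0)
            out = cols @ w2
            fwd = (0, 1 + nsp) + tuple(range(1, 1 + nsp))
            return out.transpose(fwd) + self.bias.reshape(bias_shape)
        widths = ((0, 0), (0, 0)) + tuple((p, p) for p in self.padding)
        if any(p for p in self.padding):
            x = pad(x, widths)
        return _corr_nd(x, self.weight, self.kernel) + self.bias.reshape(bias_shape)


def _pair(v, n):
    return (v,) * n if isinstance(v, int) else tuple(v)


class Conv2d(_ConvNd):
    def __init__(self, in_channels, out_channels, kernel_size, rng, stride=1, padding=0):
        super().__init__(in_channels, out_channels, _pair(kernel_size, 2), rng,
                         _pair(stride, 2), _pair(padding, 2))


class Conv3d(_ConvNd):
    def __init__(self, in_channels, out_channels, kernel_size, rng, stride=1, padding=0):
        super().__init__(in_channels, out_channels, _pair(kernel_size, 3), rng,
                         _pair(stride, 3), _pair(padding, 3))
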