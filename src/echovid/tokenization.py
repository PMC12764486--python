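"""Cube embedding, token masks, and fixed 3D sinusoidal positional encodings.

A clip of shape (T, C, H, W) is partitioned into non-overlapping
tau x h x w space-time cubes; each cube (tau*h*w*C pixels) maps through one
shared linear projection to a d_model-wide token. Tokens are ordered in a
fixed t-major raster: index = (t_bar_idx * h_bar + h_idx) * w_bar + w_idx.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ContractError, ParameterError
from .nn import Linear, Module, Tensor
from .video_io.clips import VideoClip

__all__ = [
    "CubeGridSpec",
    "TokenSequence",
    "MaskSpec",
    "seq_length",
    "cubes_from_clip",
    "clip_from_cubes",
    "CubeEmbed",
    "cube_embed",
    "make_mask",
    "positional_encoding_1d",
    "positional_encoding_3d",
]


@dataclass(frozen=True)
class CubeGridSpec:
    T: int
    tau: int
    H: int
    h: int
    W: int
    w: int
    d_model: int

    def __post_init__(self):
        for dim, stride, name in ((self.T, self.tau, "T/tau"),
                                  (self.H, self.h, "H/h"),
                                  (self.W, self.w, "W/w")):
            if stride < 1 or dim < 1:
                raise ConfigurationError(f"{name}: dims and strides must be positive")
            if dim % stride != 0:
                raise ConfigurationError(
                    f"{name}: {dim} is not divisible by {stride} (no implicit padding)")
        if self.d_model < 1:
            raise ConfigurationError("d_model must be positive")

    @property
    def t_bar(self) -> int:
        return self.T // self.tau

    @property
    def h_bar(self) -> int:
        return self.H // self.h

    @property
    def w_bar(self) -> int:
        return self.W // self.w

    @property
    def L_seq(self) -> int:
        return self.t_bar * self.h_bar * self.w_bar

    @property
    def cube_pixels(self) -> int:
        return self.tau * self.h * self.w * 3

    def to_dict(self) -> dict:
        return {"T": self.T, "tau": self.tau, "H": self.H, "h": self.h,
                "W": self.W, "w": self.w, "d_model": self.d_model}

    @classmethod
    def from_dict(cls, d: dict) -> "CubeGridSpec":
        return cls(**{k: int(d[k]) for k in ("T", "tau", "H", "h", "W", "w", "d_model")})


@dataclass
class TokenSequence:
    tokens: np.ndarray          # (L_seq, d_model)
    grid: CubeGridSpec

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.float32)
        if self.tokens.shape != (self.grid.L_seq, self.grid.d_model):
            raise ContractError(
                f"token array {self.tokens.shape} does not match grid "
                f"({self.grid.L_seq}, {self.grid.d_model})")
        if not np.isfinite(self.tokens).all():
            raise ContractError("token sequence contains non-finite values")


@dataclass(frozen=True)
class MaskSpec:
    masked: tuple[int, ...]     # sorted indices
    L_seq: int
    ratio: float
    seed: int

    def __post_init__(self):
        m = self.masked
        if list(m) != sorted(set(m)):
            raise ContractError("masked indices must be sorted and unique")
        if m and (m[0] < 0 or m[-1] >= self.L_seq):
            raise ContractError("masked index out of range")

    @property
    def visible(self) -> tuple[int, ...]:
        ms = set(self.masked)
        return tuple(i for i in range(self.L_seq) if i not in ms)

    @property
    def num_masked(self) -> int:
        return len(self.masked)


def seq_length(T: int, tau: int, H: int, h: int, W: int, w: int) -> int:
    """Token count T/tau * H/h * W/w; exact divisibility required."""
    return CubeGridSpec(T=T, tau=tau, H=H, h=h, W=W, w=w, d_model=1).L_seq


def cubes_from_clip(pixels: np.ndarray, grid: CubeGridSpec) -> np.ndarray:
    """(T, C, H, W) -> (L_seq, tau*h*w*C) in t-major raster order.

    Within a cube, pixels are flattened in (tau, h, w, C) order.
    """
    T, C, H, W = pixels.shape
    if (T, H, W) != (grid.T, grid.H, grid.W):
        raise ConfigurationError(
            f"clip shape {(T, H, W)} does not match grid {(grid.T, grid.H, grid.W)}")
    x = pixels.reshape(grid.t_bar, grid.tau, C, grid.h_bar, grid.h, grid.w_bar, grid.w)
    x = x.transpose(0, 3, 5, 1, 4, 6, 2)  # (t_bar, h_bar, w_bar, tau, h, w, C)
    return np.ascontiguousarray(x.reshape(grid.L_seq, grid.cube_pixels))


def clip_from_cubes(cubes: np.ndarray, grid: CubeGridSpec) -> np.ndarray:
    """Inverse of :func:`cubes_from_clip`."""
    x = cubes.reshape(grid.t_bar, grid.h_bar, grid.w_bar, grid.tau, grid.h, grid.w, 3)
    x = x.transpose(0, 3, 6, 1, 4, 2, 5)  # (t_bar, tau, C, h_bar, h, w_bar, w)
    return np.ascontiguousarray(x.reshape(grid.T, 3, grid.H, grid.W))


class CubeEmbed(Module):
    """Shared linear projection of each cube to a d_model token (trainable)."""

    def __init__(self, grid: CubeGridSpec, rng: np.random.Generator):
        self.grid = grid
        self.proj = Linear(grid.cube_pixels, grid.d_model, rng)

    def forward(self, clips: np.ndarray) -> Tensor:
        """(B, T, C, H, W) pixel batch -> (B, L_seq, d_model) token Tensor."""
        b = clips.shape[0]
        cubes = np.stack([cubes_from_clip(c, self.grid) for c in clips])
        return self.proj(Tensor(cubes.reshape(b, self.grid.L_seq, self.grid.cube_pixels)))


def cube_embed(clip: VideoClip, grid: CubeGridSpec,
               weight: np.ndarray, bias: np.ndarray | None = None) -> TokenSequence:
    """Functional cube embedding of one clip with explicit weights.

    `weight` has shape (cube_pixels, d_model); `bias` shape (d_model,).
    """
    weight = np.asarray(weight, dtype=np.float32)
    if weight.shape != (grid.cube_pixels, grid.d_model):
        raise ConfigurationError(
            f"weight shape {weight.shape} != ({grid.cube_pixels}, {grid.d_model})")
    cubes = cubes_from_clip(clip.pixels, grid)
    tokens = cubes @ weight
    if bias is not None:
        tokens = tokens + np.asarray(bias, dtype=np.float32)
    return TokenSequence(tokens=tokens, grid=grid)


def make_mask(L_seq: int, ratio: float, seed: int, mode: str = "uniform",
              grid: CubeGridSpec | None = None) -> MaskSpec:
    """Random token subset of size floor(ratio * L_seq).

    ``mode='uniform'`` (default) draws tokens uniformly over the whole
    space-time grid. ``mode='tube'`` masks whole temporal tubes: the same
    floor(ratio * h_bar * w_bar) spatial positions across every temporal
    slab (requires `grid`).
    """
    if not 0.0 <= ratio < 1.0:
        raise ParameterError(f"mask ratio must be in [0, 1), got {ratio}")
    if L_seq < 1:
        raise ParameterError(f"L_seq must be >= 1, got {L_seq}")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        n_masked = int(np.floor(ratio * L_seq))
        masked = sorted(rng.choice(L_seq, size=n_masked, replace=False).tolist())
    elif mode == "tube":
        if grid is None or grid.L_seq != L_seq:
            raise ParameterError("tube masking requires a matching grid spec")
        spatial = grid.h_bar * grid.w_bar
        n_spatial = int(np.floor(ratio * spatial))
        cols = rng.choice(spatial, size=n_spatial, replace=False)
        masked = sorted(int(t * spatial + c)
                        for t in range(grid.t_bar) for c in cols)
    else:
        raise ParameterError(f"unknown mask mode {mode!r}")
    return MaskSpec(masked=tuple(masked), L_seq=L_seq, ratio=ratio, seed=seed)


def positional_encoding_1d(positions: np.ndarray, d_model: int) -> np.ndarray:
    """Standard sinusoidal encoding of integer/float positions -> (N, d_model)."""
    positions = np.asarray(positions, dtype=np.float64)
    half = d_model // 2
    out = np.zeros((positions.shape[0], d_model), dtype=np.float64)
    if half > 0:
        freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half, 1))
        args = positions[:, None] * freqs[None, :]
        out[:, 0:2 * half:2] = np.sin(args)
        out[:, 1:2 * half:2] = np.cos(args)
    return out.astype(np.float32)


def positional_encoding_3d(grid: CubeGridSpec, d_model: int | None = None) -> np.ndarray:
    """Fixed sinusoidal encoding factorized over (t_bar, h_bar, w_bar).

    d_model is split into three near-equal even blocks (t, h, w); any
    remainder channels stay zero. Injective over grid positions for
    d_model >= 6.
    """
    d = d_model if d_model is not None else grid.d_model
    base = (d // 3) - ((d // 3) % 2)
    sizes = [base, base, base]
    for i in range(3):
        if sum(sizes) + 2 <= d:
            sizes[i] += 2
    dt, dh, dw = sizes
    enc = np.zeros((grid.t_bar, grid.h_bar, grid.w_bar, d), dtype=np.float32)
    et = positional_encoding_1d(np.arange(grid.t_bar), dt)
    eh = positional_encoding_1d(np.arange(grid.h_bar), dh)
    ew = positional_encoding_1d(np.arange(grid.w_bar), dw)
    enc[..., :dt] = et[:, None, None, :]
    enc[..., dt:dt + dh] = eh[None, :, None, :]
    enc[..., dt + dh:dt + dh + dw] = ew[None, None, :, :]
    return enc.reshape(grid.L_seq, d)
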