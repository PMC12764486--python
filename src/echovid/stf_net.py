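"""Dual-pathway spatio-temporal fusion over the full (unmasked) token grid.

The joint pathway treats tokens as one 3D feature volume (channels x
t_bar x h_bar x w_bar): add fixed 3D positional encodings, one 3D residual
block, then gated-attention pooling over all grid positions. The disjoint
pathway treats tokens as t_bar separate 2D maps: a 2D residual block, a
learnable-pooling convolution with kernel == stride == (h_bar, w_bar)
collapsing space, sparse temporal positional encodings built from the
original frame indices, then gated-attention pooling over time. The two
d_model vectors are concatenated into a 2*d_model fused representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ContractError
from .nn import (Conv2d, Conv3d, GroupNorm, Linear, Module, Tensor,
                 concatenate, relu, sigmoid, softmax, tanh)
from .tokenization import CubeGridSpec, TokenSequence, positional_encoding_1d, \
    positional_encoding_3d

__all__ = [
    "GatedAttentionPool",
    "ResBlock2d",
    "ResBlock3d",
    "JointPathway",
    "DisjointPathway",
    "STFNet",
    "FusedRepresentation",
    "gated_attention_pool",
    "sparse_temporal_encodings",
]


@dataclass
class FusedRepresentation:
    joint_vec: np.ndarray     # (d_model,)
    disjoint_vec: np.ndarray  # (d_model,)

    @property
    def fused(self) -> np.ndarray:
        return np.concatenate([self.joint_vec, self.disjoint_vec])


class GatedAttentionPool(Module):
    """score_k = w^T( tanh(V x_k) * sigmoid(U x_k) ); softmax over K; weighted sum."""

    def __init__(self, d_model: int, L: int, rng: np.random.Generator):
        self.V = Linear(d_model, L, rng, bias=False)
        self.U = Linear(d_model, L, rng, bias=False)
        self.w = Linear(L, 1, rng, bias=False)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """(B, K, d) -> pooled (B, d), weights (B, K)."""
        gate = tanh(self.V(x)) * sigmoid(self.U(x))       # (B, K, L)
        scores = self.w(gate)                             # (B, K, 1)
        weights = softmax(scores, axis=1)
        pooled = (weights * x).sum(axis=1)                # (B, d)
        b, k = x.shape[0], x.shape[1]
        return pooled, weights.reshape(b, k)


def gated_attention_pool(seq: np.ndarray, w: np.ndarray, U: np.ndarray,
                         V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Functional form on one sequence (K, d) with explicit parameter matrices.

    `w` is (L, 1) or (L,); `U`, `V` are (L, d).
    """
    seq = np.asarray(seq, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64).reshape(-1)
    U = np.asarray(U, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    gate = np.tanh(seq @ V.T) * (1.0 / (1.0 + np.exp(-(seq @ U.T))))
    scores = gate @ w
    scores = scores - scores.max()
    weights = np.exp(scores)
    weights /= weights.sum()
    pooled = weights @ seq
    return pooled.astype(np.float32), weights.astype(np.float32)


class _ConvNormRelu(Module):
    def __init__(self, conv: Module, channels: int, groups: int):
        self.conv = conv
        self.norm = GroupNorm(groups, channels)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.norm(self.conv(x)))


def _norm_groups(channels: int) -> int:
    for g in (8, 4, 2, 1):
        if channels % g == 0:
            return g
    return 1


class ResBlock3d(Module):
    """Three conv(3^3)->GroupNorm->ReLU stacks with one additive skip."""

    def __init__(self, channels: int, rng: np.random.Generator):
        g = _norm_groups(channels)
        self.stacks = [
            _ConvNormRelu(Conv3d(channels, channels, 3, rng, stride=1, padding=1),
                          channels, g)
            for _ in range(3)
        ]

    def forward(self, x: Tensor) -> Tensor:
        y = x
        for stack in self.stacks:
            y = stack(y)
        return x + y


class ResBlock2d(Module):
    """Three conv(3^2)->GroupNorm->ReLU stacks with one additive skip."""

    def __init__(self, channels: int, rng: np.random.Generator):
        g = _norm_groups(channels)
        self.stacks = [
            _ConvNormRelu(Conv2d(channels, channels, 3, rng, stride=1, padding=1),
                          channels, g)
            for _ in range(3)
        ]

    def forward(self, x: Tensor) -> Tensor:
        y = x
        for stack in self.stacks:
            y = stack(y)
        return x + y


def tokens_to_volume(tokens: Tensor, grid: CubeGridSpec) -> Tensor:
    """(B, L_seq, d) -> (B, d, t_bar, h_bar, w_bar) via the fixed raster bijection."""
    b = tokens.shape[0]
    x = tokens.reshape(b, grid.t_bar, grid.h_bar, grid.w_bar, grid.d_model)
    return x.transpose(0, 4, 1, 2, 3)


def volume_to_tokens(volume: Tensor, grid: CubeGridSpec) -> Tensor:
    b = volume.shape[0]
    return volume.transpose(0, 2, 3, 4, 1).reshape(b, grid.L_seq, grid.d_model)


def sparse_temporal_encodings(source_frame_indices: np.ndarray, tau: int,
                              d_model: int) -> np.ndarray:
    """Average groups of `tau` consecutive 1D frame-index encodings.

    (B, T) integer indices -> (B, T // tau, d_model). For tau == 2 this is
    the adjacent-pair averaging of the original frame-index encodings.
    """
    idx = np.asarray(source_frame_indices)
    if idx.ndim == 1:
        idx = idx[None]
    b, T = idx.shape
    if T % tau != 0:
        raise ConfigurationError(f"frame count {T} not divisible by tau {tau}")
    enc = np.stack([positional_encoding_1d(row, d_model) for row in idx])  # (B, T, d)
    return enc.reshape(b, T // tau, tau, d_model).mean(axis=2)


class _SparseEncodingHead(Module):
    """Two linear transformations interspersed with a ReLU."""

    def __init__(self, d_model: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_model, rng)
        self.fc2 = Linear(d_model, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(x)))


class JointPathway(Module):
    def __init__(self, grid: CubeGridSpec, L: int, rng: np.random.Generator,
                 use_positional: bool = True):
        self.grid = grid
        self.use_positional = use_positional
        self.res = ResBlock3d(grid.d_model, rng)
        self.pool = GatedAttentionPool(grid.d_model, L, rng)
        pe = positional_encoding_3d(grid)                 # (L_seq, d)
        self.pos_enc = pe.reshape(grid.t_bar, grid.h_bar, grid.w_bar,
                                  grid.d_model).transpose(3, 0, 1, 2)

    def forward(self, tokens: Tensor) -> tuple[Tensor, Tensor]:
        vol = tokens_to_volume(tokens, self.grid)
        if self.use_positional:
            vol = vol + Tensor(self.pos_enc[None])
        vol = self.res(vol)
        seq = volume_to_tokens(vol, self.grid)
        return self.pool(seq)


class DisjointPathway(Module):
    def __init__(self, grid: CubeGridSpec, L: int, rng: np.random.Generator):
        self.grid = grid
        d = grid.d_model
        self.res = ResBlock2d(d, rng)
        self.spatial_pool = Conv2d(d, d, (grid.h_bar, grid.w_bar), rng,
                                   stride=(grid.h_bar, grid.w_bar), padding=0)
        self.enc_head = _SparseEncodingHead(d, rng)
        self.pool = GatedAttentionPool(d, L, rng)

    def forward(self, tokens: Tensor,
                source_frame_indices: np.ndarray) -> tuple[Tensor, Tensor]:
        grid = self.grid
        idx = np.asarray(source_frame_indices)
        if idx.ndim == 1:
            idx = idx[None]
        if idx.shape[-1] != grid.T:
            raise ConfigurationError(
                f"need {grid.T} frame indices per clip, got {idx.shape[-1]}")
        b = tokens.shape[0]
        maps = tokens.reshape(b, grid.t_bar, grid.h_bar, grid.w_bar, grid.d_model)
        maps = maps.transpose(0, 1, 4, 2, 3).reshape(
            b * grid.t_bar, grid.d_model, grid.h_bar, grid.w_bar)
        maps = self.res(maps)
        vecs = self.spatial_pool(maps)                    # (B*t_bar, d, 1, 1)
        vecs = vecs.reshape(b, grid.t_bar, grid.d_model)
        sparse = sparse_temporal_encodings(idx, grid.tau, grid.d_model)
        if sparse.shape[1] != grid.t_bar:
            raise ConfigurationError(
                f"sparse encodings count {sparse.shape[1]} != t_bar {grid.t_bar}")
        vecs = vecs + self.enc_head(Tensor(np.broadcast_to(
            sparse, (b, grid.t_bar, grid.d_model)).copy()))
        return self.pool(vecs)


class STFNet(Module):
    """Joint + disjoint pathways; output fused width 2 * d_model."""

    def __init__(self, grid: CubeGridSpec, L: int = 1024, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.grid = grid
        self.joint = JointPathway(grid, L, rng)
        self.disjoint = DisjointPathway(grid, L, rng)

    def forward(self, tokens: Tensor,
                source_frame_indices: np.ndarray) -> Tensor:
        jv, _ = self.joint(tokens)
        dv, _ = self.disjoint(tokens, source_frame_indices)
        return concatenate([jv, dv], axis=-1)

    def fuse_sequence(self, seq: TokenSequence,
                      source_frame_indices) -> FusedRepresentation:
        """Spec-level single-clip fusion returning both pathway vectors."""
        if seq.grid != self.grid:
            raise ContractError("token sequence grid does not match STF-Net grid")
        tokens = Tensor(seq.tokens[None])
        jv, _ = self.joint(tokens)
        dv, _ = self.disjoint(tokens, np.asarray(source_frame_indices))
        return FusedRepresentation(joint_vec=jv.data[0].copy(),
                                   disjoint_vec=dv.data[0].copy())
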