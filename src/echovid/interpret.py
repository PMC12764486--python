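"""Attention-rollout saliency for encoders without a [CLS] token.

Per-layer head-averaged attention matrices are mixed with the identity
(residual coefficient 0.5), row-renormalized, and multiplied in layer
order. One row of the rolled matrix, reshaped onto the cube grid and
bilinearly upsampled, gives a per-frame saliency overlay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage.transform import resize as _sk_resize

from .errors import ContractError, ParameterError
from .tokenization import CubeGridSpec
from .video_io.avi import write_avi
from .video_io.clips import VideoClip

__all__ = ["SaliencyMap", "attention_rollout", "row_saliency", "overlay"]


@dataclass
class SaliencyMap:
    grid_saliency: np.ndarray   # (t_bar, h_bar, w_bar), non-negative
    frame_maps: np.ndarray      # (T, H, W), non-negative

    def __post_init__(self):
        if (self.grid_saliency < 0).any() or (self.frame_maps < 0).any():
            raise ContractError("saliency must be non-negative")
        if not (np.isfinite(self.grid_saliency).all()
                and np.isfinite(self.frame_maps).all()):
            raise ContractError("saliency must be finite")


def attention_rollout(per_layer_attention: np.ndarray,
                      residual_coeff: float = 0.5) -> np.ndarray:
    """(depth, L, L) row-stochastic matrices -> rolled (L, L) matrix."""
    atts = np.asarray(per_layer_attention, dtype=np.float64)
    if atts.ndim != 3 or atts.shape[1] != atts.shape[2]:
        raise ContractError(f"expected (depth, L, L), got {atts.shape}")
    if not np.allclose(atts.sum(axis=-1), 1.0, atol=1e-4):
        raise ContractError("attention rows must be probability distributions")
    L = atts.shape[1]
    rolled = np.eye(L)
    eye = np.eye(L)
    for layer in atts:
        mixed = residual_coeff * layer + (1.0 - residual_coeff) * eye
        mixed = mixed / mixed.sum(axis=-1, keepdims=True)
        rolled = mixed @ rolled
    return rolled


def row_saliency(rolled: np.ndarray, i: int, grid: CubeGridSpec,
                 H: int, W: int) -> SaliencyMap:
    """Row i reshaped to the cube grid; each temporal slab upsampled to H x W.

    Every slab is copied to its tau source frames (no temporal interpolation).
    """
    rolled = np.asarray(rolled, dtype=np.float64)
    L = grid.L_seq
    if rolled.shape != (L, L):
        raise ContractError(f"rolled matrix {rolled.shape} != ({L}, {L})")
    if not 0 <= i < L:
        raise ParameterError(f"token index {i} out of range [0, {L})")
    vol = rolled[i].reshape(grid.t_bar, grid.h_bar, grid.w_bar)
    frames = np.empty((grid.T, H, W), dtype=np.float64)
    for t_bar_idx in range(grid.t_bar):
        up = _sk_resize(vol[t_bar_idx], (H, W), order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
        up = np.clip(up, 0.0, None)
        for k in range(grid.tau):
            frames[t_bar_idx * grid.tau + k] = up
    return SaliencyMap(grid_saliency=vol.copy(), frame_maps=frames)


def _normalize_per_frame(maps: np.ndarray) -> np.ndarray:
    out = np.empty_like(maps)
    for t in range(maps.shape[0]):
        peak = maps[t].max()
        out[t] = maps[t] / peak if peak > 0 else maps[t]
    return out


def overlay(clip: VideoClip, maps: SaliencyMap, out_dir,
            alpha: float = 0.6) -> dict:
    """Write per-frame PNG overlays plus an AVI; deterministic given inputs.

    Saliency is max-normalized per frame and blended into the red channel.
    Returns {'pngs': [...], 'avi': path}.
    """
    T = clip.num_frames
    H, W = clip.frame_shape
    if maps.frame_maps.shape != (T, H, W):
        raise ContractError(
            f"saliency {maps.frame_maps.shape} does not match clip {(T, H, W)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sal = _normalize_per_frame(maps.frame_maps)
    frames_u8 = np.empty((T, H, W, 3), dtype=np.uint8)
    for t in range(T):
        rgb = clip.pixels[t].transpose(1, 2, 0).astype(np.float64)
        s = sal[t][..., None]
        blended = rgb.copy()
        blended[..., 0] = np.clip(rgb[..., 0] * (1 - alpha * s[..., 0])
                                  + alpha * s[..., 0], 0, 1)
        blended[..., 1] = rgb[..., 1] * (1 - alpha * s[..., 0])
        blended[..., 2] = rgb[..., 2] * (1 - alpha * s[..., 0])
        frames_u8[t] = np.round(np.clip(blended, 0, 1) * 255).astype(np.uint8)
    pngs = []
    for t in range(T):
        png_path = out_dir / f"frame_{t:03d}.png"
        iio.imwrite(png_path, frames_u8[t])
        pngs.append(png_path)
    avi_path = out_dir / "overlay.avi"
    write_avi(avi_path, frames_u8)
    return {"pngs": pngs, "avi": avi_path}
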