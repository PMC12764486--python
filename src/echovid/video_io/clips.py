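"""Clip-level operations: decoding, temporal sampling, resizing, augmentation.

A :class:`VideoClip` is the unit of data everywhere downstream: a float32
(T, 3, H, W) pixel array in [0, 1] plus the raw-video frame indices each
sampled frame came from (used later for sparse temporal encodings).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from ..errors import DataError, EmptyVideoError, ParameterError
from .avi import read_avi

__all__ = [
    "VideoClip",
    "read_video",
    "uniform_temporal_sample",
    "resize_and_normalize",
    "random_horizontal_flip",
]


@dataclass
class VideoClip:
    pixels: np.ndarray                  # (T, 3, H, W) float32 in [0, 1]
    source_frame_indices: list[int]
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 4:
            raise DataError(f"clip must be rank-4, got shape {self.pixels.shape}")
        t, c = self.pixels.shape[:2]
        if t < 1:
            raise DataError("clip must contain at least one frame")
        if c != 3:
            raise DataError(f"clip must have 3 channels, got {c}")
        if len(self.source_frame_indices) != t:
            raise DataError("source_frame_indices length must equal frame count")
        idx = list(self.source_frame_indices)
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise DataError("source_frame_indices must be non-decreasing")
        if not np.isfinite(self.pixels).all():
            raise DataError("clip contains non-finite pixels")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise DataError("clip pixels must lie in [0, 1]")

    @property
    def num_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]


def read_video(path) -> np.ndarray:
    """Decode a video file into a float32 (T_raw, 3, H, W) stack in [0, 1].

    Grayscale sources are replicated to three identical channels.
    """
    path = Path(path)
    frames = read_avi(path)  # (T, H, W, 3) uint8; raises DecodeError / EmptyVideoError
    stack = frames.astype(np.float32) / 255.0
    return np.ascontiguousarray(stack.transpose(0, 3, 1, 2))


def uniform_temporal_sample(frames: np.ndarray, T: int, source_id: str = "") -> VideoClip:
    """Pick T frames at indices floor(k * T_raw / T), k = 0..T-1.

    When T_raw < T the rule naturally repeats frames (padding by repetition).
    """
    if T < 1:
        raise ParameterError(f"T must be >= 1, got {T}")
    frames = np.asarray(frames, dtype=np.float32)
    t_raw = frames.shape[0]
    if t_raw == 0:
        raise EmptyVideoError("cannot sample from a zero-frame video")
    indices = [int(k * t_raw // T) for k in range(T)]
    return VideoClip(pixels=frames[indices], source_frame_indices=indices,
                     source_id=source_id)


def resize_and_normalize(clip: VideoClip, H: int, W: int) -> VideoClip:
    """Bilinearly resize every frame to H x W; clamp back into [0, 1]."""
    if H < 1 or W < 1:
        raise ParameterError(f"target size must be positive, got {H}x{W}")
    if not np.isfinite(clip.pixels).all():
        raise DataError("clip contains non-finite pixels")
    if clip.frame_shape == (H, W):
        return VideoClip(pixels=clip.pixels.copy(),
                         source_frame_indices=list(clip.source_frame_indices),
                         source_id=clip.source_id)
    t = clip.num_frames
    # resize frame-by-frame; order=1 is bilinear
    out = np.empty((t, H, W, 3), dtype=np.float32)
    src = clip.pixels.transpose(0, 2, 3, 1)
    for i in range(t):
        out[i] = _sk_resize(src[i], (H, W), order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True)
    out = np.clip(out, 0.0, 1.0)
    return VideoClip(pixels=np.ascontiguousarray(out.transpose(0, 3, 1, 2)),
                     source_frame_indices=list(clip.source_frame_indices),
                     source_id=clip.source_id)


def random_horizontal_flip(clip: VideoClip, p: float, seed: int) -> VideoClip:
    """With seeded probability p, mirror every frame on the width axis."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"flip probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    if rng.random() < p:
        pixels = np.ascontiguousarray(clip.pixels[:, :, :, ::-1])
    else:
        pixels = clip.pixels.copy()
    return VideoClip(pixels=pixels,
                     source_frame_indices=list(clip.source_frame_indices),
                     source_id=clip.source_id)
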