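"""Synthetic ultrasound-like phantoms with analytically known labels.

Each phantom is a dark elliptical chamber beating inside a bright,
speckle-textured scan sector. The chamber's semi-axes shrink from their
end-diastolic values by a known fractional ``contraction`` at end-systole,
following a raised-cosine profile within each cardiac cycle. Volumes use
the single-plane ellipsoid proxy Vol = scale * a * b^2, which makes the
ejection fraction an exact function of the contraction:

    EF = 100 * (1 - (1 - contraction)^3)

so regression targets are recoverable by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .video_io.avi import write_avi
from .video_io.clips import VideoClip
from .video_io.manifest import DatasetManifest, ManifestRecord

__all__ = [
    "PhantomParams",
    "LabeledClip",
    "ejection_fraction_from_contraction",
    "generate_phantom",
    "generate_dataset",
    "split_counts",
]

#: converts pixel^3 ellipsoid products into "ml-equivalent" volumes
VOLUME_SCALE = 1.0 / 250.0


@dataclass
class PhantomParams:
    T_raw: int = 32
    H: int = 32
    W: int = 32
    cycle_length: int = 16
    a_ED: float = 10.0
    b_ED: float = 7.0
    contraction: float = 0.3
    speckle_sigma: float = 0.15
    sector_angle: float = 75.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.contraction < 1.0:
            raise ParameterError(f"contraction must be in (0, 1), got {self.contraction}")
        if self.a_ED <= 0 or self.b_ED <= 0:
            raise ParameterError("end-diastolic semi-axes must be positive")
        if self.cycle_length < 2:
            raise ParameterError(f"cycle_length must be >= 2, got {self.cycle_length}")
        if self.speckle_sigma < 0:
            raise ParameterError("speckle_sigma must be >= 0")
        if self.T_raw < 1 or self.H < 1 or self.W < 1:
            raise ParameterError("T_raw, H, W must be positive")


@dataclass
class LabeledClip:
    clip: VideoClip
    ef: float    # percent
    esv: float   # ml-equivalent
    edv: float   # ml-equivalent

    def __post_init__(self):
        if not (0.0 < self.ef < 100.0):
            raise ParameterError(f"EF must be in (0, 100), got {self.ef}")
        if not (self.edv > self.esv > 0.0):
            raise ParameterError("volumes must satisfy edv > esv > 0")
        if abs(self.ef - 100.0 * (self.edv - self.esv) / self.edv) > 1e-9:
            raise ParameterError("EF inconsistent with volumes")


def ejection_fraction_from_contraction(contraction: float) -> float:
    """EF in percent implied by a fractional semi-axis contraction."""
    return 100.0 * (1.0 - (1.0 - contraction) ** 3)


def _sector_mask(H: int, W: int, angle_deg: float) -> np.ndarray:
    """Fan-shaped mask with apex at the top-center of the frame."""
    ys, xs = np.mgrid[0:H, 0:W].astype(np.float32)
    dy = ys + 1.0
    dx = xs - (W - 1) / 2.0
    theta = np.arctan2(dx, dy)  # 0 points straight down
    half = math.radians(angle_deg / 2.0)
    radius = np.hypot(dx, dy)
    return (np.abs(theta) <= half) & (radius <= 1.05 * H)


def generate_phantom(params: PhantomParams) -> LabeledClip:
    """Render one labeled phantom video (grayscale replicated to RGB)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    H, W, T = params.H, params.W, params.T_raw

    sector = _sector_mask(H, W, params.sector_angle)
    ys, xs = np.mgrid[0:H, 0:W].astype(np.float32)
    cy, cx = 0.55 * H, 0.5 * W

    frames = np.empty((T, H, W), dtype=np.float32)
    for t in range(T):
        phase = (t % params.cycle_length) / params.cycle_length
        s = 0.5 * (1.0 - math.cos(2.0 * math.pi * phase))  # 0 at ED, 1 at ES
        shrink = 1.0 - params.contraction * s
        a = params.a_ED * shrink
        b = params.b_ED * shrink
        inside = ((ys - cy) / a) ** 2 + ((xs - cx) / b) ** 2 <= 1.0
        frame = np.full((H, W), 0.60, dtype=np.float32)
        frame[inside] = 0.15
        if params.speckle_sigma > 0:
            g = rng.standard_normal((H, W)).astype(np.float32)
            frame = frame * np.exp(params.speckle_sigma * g)
        frame[~sector] = 0.0
        frames[t] = np.clip(frame, 0.0, 1.0)

    pixels = np.repeat(frames[:, None, :, :], 3, axis=1)
    clip = VideoClip(pixels=pixels, source_frame_indices=list(range(T)),
                     source_id=f"phantom-seed{params.seed}")

    edv = VOLUME_SCALE * params.a_ED * params.b_ED ** 2
    shrink_es = 1.0 - params.contraction
    esv = edv * shrink_es ** 3
    ef = 100.0 * (edv - esv) / edv
    return LabeledClip(clip=clip, ef=ef, esv=esv, edv=edv)


def split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """floor(train), floor(val), remainder to test."""
    f_tr, f_val, f_te = fractions
    if min(fractions) < 0 or abs(f_tr + f_val + f_te - 1.0) > 1e-9:
        raise ParameterError(f"split fractions must be >= 0 and sum to 1, got {fractions}")
    n_tr = int(math.floor(f_tr * n))
    n_val = int(math.floor(f_val * n))
    return n_tr, n_val, n - n_tr - n_val


def generate_dataset(n: int, out_dir, seed: int = 0,
                     contraction_range: tuple[float, float] = (0.1, 0.6),
                     param_ranges: dict | None = None,
                     split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                     base_params: PhantomParams | None = None,
                     write_clips: bool = True) -> tuple[DatasetManifest, list[LabeledClip]]:
    """Generate `n` labeled phantom clips + a manifest under `out_dir`.

    Contraction is drawn uniformly from ``contraction_range`` (a degenerate
    range pins every label). ``param_ranges`` may map any of
    ``a_ED``/``b_ED``/``speckle_sigma`` to a (lo, hi) uniform range so chamber
    geometry varies per clip; EF stays an exact function of contraction while
    per-frame pixel statistics stop being a shortcut for it. The split
    assignment is deterministic under ``seed``: floor(f*n) records for train
    and val, the remainder to test, assigned after a seeded shuffle of clip
    order.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    lo, hi = contraction_range
    if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0 and lo <= hi):
        raise ParameterError(f"contraction range must lie in (0, 1), got {contraction_range}")
    base = base_params or PhantomParams()
    param_ranges = dict(param_ranges or {})
    unknown = set(param_ranges) - {"a_ED", "b_ED", "speckle_sigma"}
    if unknown:
        raise ParameterError(f"unsupported param_ranges keys: {sorted(unknown)}")
    out_dir = Path(out_dir)
    if write_clips:
        out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    contractions = rng.uniform(lo, hi, size=n) if lo < hi else np.full(n, lo)
    varied = {name: rng.uniform(r[0], r[1], size=n)
              for name, r in param_ranges.items()}
    clip_seeds = rng.integers(0, 2**31 - 1, size=n)

    n_tr, n_val, n_te = split_counts(n, split_fractions)
    splits = ["train"] * n_tr + ["val"] * n_val + ["test"] * n_te
    order = rng.permutation(n)
    assigned = [""] * n
    for rank, idx in enumerate(order):
        assigned[idx] = splits[rank]

    records: list[ManifestRecord] = []
    labeled: list[LabeledClip] = []
    for i in range(n):
        params = PhantomParams(
            T_raw=base.T_raw, H=base.H, W=base.W, cycle_length=base.cycle_length,
            a_ED=float(varied["a_ED"][i]) if "a_ED" in varied else base.a_ED,
            b_ED=float(varied["b_ED"][i]) if "b_ED" in varied else base.b_ED,
            contraction=float(contractions[i]),
            speckle_sigma=(float(varied["speckle_sigma"][i])
                           if "speckle_sigma" in varied else base.speckle_sigma),
            sector_angle=base.sector_angle, seed=int(clip_seeds[i]))
        lc = generate_phantom(params)
        labeled.append(lc)
        rel = f"clip_{i:05d}.avi"
        if write_clips:
            gray = (lc.clip.pixels[:, 0] * 255.0).round().astype(np.uint8)
            write_avi(out_dir / rel, gray)
        records.append(ManifestRecord(
            path=str(out_dir / rel), split=assigned[i],
            labels={"LV_EF": lc.ef, "LV_ESV": lc.esv, "LV_EDV": lc.edv}))

    manifest = DatasetManifest(records)
    if write_clips:
        manifest.save(out_dir / "manifest.csv")
    return manifest, labeled
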