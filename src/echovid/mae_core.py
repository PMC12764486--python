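"""Asymmetric masked video auto-encoder and its pre-training loop.

The encoder (12 joint space-time attention layers at full scale) sees only
the visible tokens plus their positional encodings; a shallow decoder
(4 layers) rebuilds the full cube grid from the encoded visible tokens and
a learnable mask token, and is trained with mean squared error over the
masked cubes only.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .checkpoint import load_checkpoint, save_checkpoint
from .errors import ContractError, DataError, ParameterError
from .nn import (AdamW, LayerNorm, Linear, Module, Tensor, TransformerBlock)
from .tokenization import (CubeEmbed, CubeGridSpec, MaskSpec, TokenSequence,
                           clip_from_cubes, cubes_from_clip, make_mask,
                           positional_encoding_3d)
from .video_io.clips import VideoClip

__all__ = [
    "EncoderConfig",
    "PretrainState",
    "VideoEncoder",
    "MaskedAutoencoder",
    "encode_visible",
    "decode_full",
    "reconstruction_loss",
    "lr_schedule",
    "run_pretraining",
]


@dataclass
class EncoderConfig:
    depth: int = 12
    d_model: int = 768
    heads: int = 12
    mlp_ratio: float = 4.0
    decoder_depth: int = 4
    decoder_width: int | None = None    # default: d_model // 2
    decoder_heads: int | None = None    # default: heads // 2 (min 1)

    def __post_init__(self):
        if self.depth < 1 or self.decoder_depth < 1:
            raise ParameterError("encoder/decoder depth must be >= 1")
        if self.d_model % self.heads != 0:
            raise ParameterError(
                f"d_model {self.d_model} not divisible by heads {self.heads}")
        if self.decoder_width is None:
            self.decoder_width = self.d_model // 2
        if self.decoder_heads is None:
            self.decoder_heads = max(1, self.heads // 2)
        if self.decoder_width % self.decoder_heads != 0:
            raise ParameterError("decoder_width not divisible by decoder_heads")

    def to_dict(self) -> dict:
        return {"depth": self.depth, "d_model": self.d_model, "heads": self.heads,
                "mlp_ratio": self.mlp_ratio, "decoder_depth": self.decoder_depth,
                "decoder_width": self.decoder_width,
                "decoder_heads": self.decoder_heads}

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        return cls(**d)


@dataclass
class PretrainState:
    peak_lr: float = 1e-4
    warmup_fraction: float = 0.05
    warmup_init_lr: float = 1e-5
    floor_lr: float = 0.0
    betas: tuple[float, float] = (0.9, 0.95)
    weight_decay: float = 0.05
    epochs: int = 30
    batch_size: int = 8
    mask_ratio: float = 0.85
    mask_mode: str = "uniform"          # "uniform" | "tube"
    per_cube_norm: bool = False         # normalize reconstruction targets
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ParameterError("warmup_fraction must be in (0, 1)")
        if min(self.peak_lr, self.warmup_init_lr, self.floor_lr) < 0:
            raise ParameterError("learning rates must be >= 0")


class VideoEncoder(Module):
    """Joint space-time attention transformer over (a subset of) tokens."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.blocks = [TransformerBlock(cfg.d_model, cfg.heads, cfg.mlp_ratio, rng)
                       for _ in range(cfg.depth)]
        self.norm = LayerNorm(cfg.d_model)

    def forward(self, tokens: Tensor, store_attention: bool = False) -> Tensor:
        x = tokens
        for block in self.blocks:
            x = block(x, store_attention=store_attention)
        return self.norm(x)

    def attention_stack(self) -> np.ndarray:
        """Per-layer head-averaged attention from the last stored forward."""
        mats = []
        for block in self.blocks:
            if block.attn.last_attention is None:
                raise ContractError("no stored attention; run forward(store_attention=True)")
            mats.append(block.attn.last_attention[0])
        return np.stack(mats)


class MaskedAutoencoder(Module):
    """Cube embedding + visible-token encoder + full-grid shallow decoder."""

    def __init__(self, grid: CubeGridSpec, cfg: EncoderConfig, seed: int = 0):
        if cfg.d_model != grid.d_model:
            raise ContractError(
                f"grid d_model {grid.d_model} != encoder d_model {cfg.d_model}")
        rng = np.random.default_rng(seed)
        self.grid = grid
        self.cfg = cfg
        self.embed = CubeEmbed(grid, rng)
        self.encoder = VideoEncoder(cfg, rng)
        dw = cfg.decoder_width
        self.enc_to_dec = Linear(cfg.d_model, dw, rng)
        self.mask_token = Tensor(rng.normal(0.0, 0.02, size=(dw,)), requires_grad=True)
        self.dec_blocks = [TransformerBlock(dw, cfg.decoder_heads, cfg.mlp_ratio, rng)
                           for _ in range(cfg.decoder_depth)]
        self.dec_norm = LayerNorm(dw)
        self.pixel_head = Linear(dw, grid.cube_pixels, rng)
        # fixed sinusoidal encodings, not trained
        self.pos_enc = positional_encoding_3d(grid, cfg.d_model)
        self.dec_pos_enc = positional_encoding_3d(grid, dw)

    # -- forward pieces -----------------------------------------------
    def encode_visible_batch(self, clips: np.ndarray, mask: MaskSpec,
                             store_attention: bool = False) -> Tensor:
        """(B, T, C, H, W) -> (B, |visible|, d_model); masked tokens never enter."""
        if mask.L_seq != self.grid.L_seq:
            raise ContractError(
                f"mask L_seq {mask.L_seq} != grid L_seq {self.grid.L_seq}")
        visible = list(mask.visible)
        tokens = self.embed(clips)                       # (B, L, d)
        vis = tokens[:, visible, :] + Tensor(self.pos_enc[visible])
        return self.encoder(vis, store_attention=store_attention)

    def decode_full_batch(self, visible_reps: Tensor, mask: MaskSpec) -> Tensor:
        """Visible reps + mask tokens -> per-cube pixel predictions (B, L, cube_pixels)."""
        visible = list(mask.visible)
        if visible_reps.shape[1] != len(visible):
            raise ContractError(
                f"visible reps length {visible_reps.shape[1]} != {len(visible)}")
        b = visible_reps.shape[0]
        L, dw = self.grid.L_seq, self.cfg.decoder_width
        dec_vis = self.enc_to_dec(visible_reps)          # (B, |v|, dw)
        scatter = np.zeros((L, len(visible)), dtype=np.float32)
        scatter[visible, np.arange(len(visible))] = 1.0
        placed = Tensor(scatter) @ dec_vis               # (B, L, dw), zeros at masked
        mask_flags = np.zeros((L, 1), dtype=np.float32)
        mask_flags[list(mask.masked)] = 1.0
        placed = placed + Tensor(mask_flags) * self.mask_token.reshape(1, dw)
        x = placed + Tensor(self.dec_pos_enc)
        for block in self.dec_blocks:
            x = block(x)
        return self.pixel_head(self.dec_norm(x))

    def reconstruct_batch(self, clips: np.ndarray, mask: MaskSpec) -> Tensor:
        reps = self.encode_visible_batch(clips, mask)
        return self.decode_full_batch(reps, mask)

    def pretrain_loss(self, clips: np.ndarray, mask: MaskSpec,
                      per_cube_norm: bool = False) -> Tensor:
        """Masked-cube MSE; visible cubes contribute nothing.

        `per_cube_norm` switches the target from raw pixels (default) to
        per-cube standardized pixels.
        """
        if mask.num_masked == 0:
            raise ParameterError("loss undefined for an empty mask (ratio 0)")
        pred = self.reconstruct_batch(clips, mask)       # (B, L, cube_pixels)
        target = np.stack([cubes_from_clip(c, self.grid) for c in clips])
        midx = list(mask.masked)
        target = target[:, midx, :]
        if per_cube_norm:
            mu = target.mean(axis=-1, keepdims=True)
            sd = target.std(axis=-1, keepdims=True) + 1e-6
            target = (target - mu) / sd
        diff = pred[:, midx, :] - Tensor(target)
        return (diff * diff).mean()


# ---------------------------------------------------------------------
# spec-level single-clip operations
# ---------------------------------------------------------------------

def encode_visible(model: MaskedAutoencoder, tokens: TokenSequence,
                   mask: MaskSpec) -> np.ndarray:
    """Run the encoder over the visible subset of a ready-made token sequence."""
    if mask.L_seq != tokens.grid.L_seq:
        raise ContractError("mask/sequence length mismatch")
    visible = list(mask.visible)
    vis = tokens.tokens[visible] + model.pos_enc[visible]
    return model.encoder(Tensor(vis[None])).data[0]


def decode_full(model: MaskedAutoencoder, visible_reps: np.ndarray,
                mask: MaskSpec) -> VideoClip:
    """Decode visible representations (+ mask tokens) back to a full clip."""
    out = model.decode_full_batch(Tensor(np.asarray(visible_reps)[None]), mask)
    pixels = clip_from_cubes(out.data[0], model.grid)
    return VideoClip(pixels=np.clip(pixels, 0.0, 1.0),
                     source_frame_indices=list(range(model.grid.T)),
                     source_id="reconstruction")


def reconstruction_loss(clip: VideoClip, recon: VideoClip, mask: MaskSpec,
                        grid: CubeGridSpec) -> float:
    """Mean squared pixel error over the masked cubes only."""
    if clip.pixels.shape != recon.pixels.shape:
        raise ContractError("clip/reconstruction shape mismatch")
    if mask.num_masked == 0:
        raise ParameterError("loss undefined for an empty mask (ratio 0)")
    target = cubes_from_clip(clip.pixels, grid)
    pred = cubes_from_clip(recon.pixels, grid)
    midx = list(mask.masked)
    diff = pred[midx] - target[midx]
    return float(np.mean(diff * diff))


def lr_schedule(step: int, total_steps: int, state: PretrainState) -> float:
    """Linear warmup over the first `warmup_fraction` of steps, then cosine."""
    if not 0 <= step <= total_steps:
        raise ParameterError(f"step {step} outside [0, {total_steps}]")
    warmup = state.warmup_fraction * total_steps
    if warmup > 0 and step <= warmup:
        frac = step / warmup
        return state.warmup_init_lr + frac * (state.peak_lr - state.warmup_init_lr)
    progress = (step - warmup) / max(total_steps - warmup, 1e-12)
    cos = 0.5 * (1.0 + math.cos(math.pi * progress))
    return state.floor_lr + (state.peak_lr - state.floor_lr) * cos


@dataclass
class PretrainResult:
    checkpoint_path: Path
    loss_history: list[float]
    lr_history: list[float]


def run_pretraining(clips: np.ndarray, grid: CubeGridSpec, cfg: EncoderConfig,
                    state: PretrainState, out_dir, total_steps: int | None = None,
                    resume_from=None, log_every: int = 1) -> PretrainResult:
    """Pre-train on an in-memory clip stack (N, T, C, H, W) in [0, 1].

    `total_steps` overrides epochs*ceil(N/batch) for short runs. Writes a
    CSV log (step, lr, loss) and a final checkpoint; deterministic under
    `state.seed`.
    """
    clips = np.asarray(clips, dtype=np.float32)
    if clips.ndim != 5 or clips.shape[0] < 1:
        raise DataError("need a non-empty (N, T, C, H, W) clip stack")
    n = clips.shape[0]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    model = MaskedAutoencoder(grid, cfg, seed=state.seed)
    opt = AdamW(model.parameters(), lr=state.peak_lr, betas=state.betas,
                weight_decay=state.weight_decay)
    start_step = 0
    if resume_from is not None:
        sd, meta, opt_state = load_checkpoint(resume_from)
        model.load_state_dict(sd)
        if opt_state:
            opt.load_state_dict(opt_state)
        start_step = int(meta.get("step", 0))

    steps_per_epoch = int(math.ceil(n / state.batch_size))
    total = total_steps if total_steps is not None else state.epochs * steps_per_epoch

    rng = np.random.default_rng(state.seed + 1)
    # replay rng decisions consumed before the resume point
    for _ in range(start_step):
        rng.integers(0, 2**31 - 1)
        rng.choice(n, size=min(state.batch_size, n), replace=n < state.batch_size)

    loss_hist: list[float] = []
    lr_hist: list[float] = []
    log_path = out_dir / "pretrain_log.csv"
    mode = "a" if (resume_from is not None and log_path.exists()) else "w"
    with open(log_path, mode, newline="") as fh:
        writer = csv.writer(fh)
        if mode == "w":
            writer.writerow(["step", "lr", "loss"])
        for step in range(start_step, total):
            mask_seed = int(rng.integers(0, 2**31 - 1))
            batch_idx = rng.choice(n, size=min(state.batch_size, n),
                                   replace=n < state.batch_size)
            batch = clips[batch_idx]
            mask = make_mask(grid.L_seq, state.mask_ratio, mask_seed,
                             mode=state.mask_mode, grid=grid)
            lr = lr_schedule(step, total, state)
            opt.lr = lr
            loss = model.pretrain_loss(batch, mask,
                                       per_cube_norm=state.per_cube_norm)
            opt.zero_grad()
            loss.backward()
            opt.step()
            loss_hist.append(float(loss.data))
            lr_hist.append(lr)
            if step % log_every == 0:
                writer.writerow([step, f"{lr:.8g}", f"{float(loss.data):.8g}"])

    ckpt_path = out_dir / "pretrain_checkpoint.npz"
    meta = {"kind": "pretrain", "grid": grid.to_dict(), "encoder": cfg.to_dict(),
            "seed": state.seed, "step": total, "mask_ratio": state.mask_ratio}
    save_checkpoint(ckpt_path, model.state_dict(), meta, opt.state_dict())
    return PretrainResult(checkpoint_path=ckpt_path, loss_history=loss_hist,
                          lr_history=lr_hist)
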