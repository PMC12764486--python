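"""Reduced-scale experiment recipes runnable on one CPU.

These mirror the full-scale study design — self-supervised pre-training on
unlabeled clips, then fine-tuning small labeled subsets with and without the
fusion network — on the synthetic phantom task, where EF labels are exact
functions of the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .checkpoint import load_checkpoint
from .mae_core import EncoderConfig, MaskedAutoencoder, PretrainState, \
    run_pretraining
from .nn import AdamW, Linear, Module, Tensor
from .stf_net import STFNet
from .synthetic_echo import PhantomParams, generate_dataset
from .tasks_eval import FitOptions, TaskSpec, finetune, regression_metrics
from .tokenization import CubeGridSpec
from .video_io.clips import uniform_temporal_sample

__all__ = ["RecoverySetup", "build_recovery_data", "pretrain_recovery_encoder",
           "run_recovery_contrasts", "frozen_feature_contrast"]

#: tiny-profile sizes with a fine spatial cube stride; 4x4 cubes keep the
#: 96-pixel cube content nearly losslessly in 64 embedding dims, which the
#: downstream contrasts need (8x8 cubes discard boundary detail).
RECOVERY_GRID = CubeGridSpec(T=8, tau=2, H=32, h=4, W=32, w=4, d_model=64)
RECOVERY_CFG = EncoderConfig(depth=2, d_model=64, heads=4, mlp_ratio=2.0,
                             decoder_depth=1, decoder_width=32, decoder_heads=2)


@dataclass
class RecoverySetup:
    n_clips: int = 300
    n_labeled: int = 32
    pretrain_steps: int = 800
    finetune_epochs: int = 45
    finetune_lr: float = 2e-3
    batch_size: int = 8
    stf_L: int = 128
    speckle_sigma: float = 0.35
    seeds: tuple[int, ...] = (0, 1, 2, 3)


def build_recovery_data(seed: int, setup: RecoverySetup) -> dict:
    """300 geometry-varied phantoms decoded to the recovery grid, per split."""
    base = PhantomParams(T_raw=24, H=32, W=32, cycle_length=12,
                         speckle_sigma=setup.speckle_sigma)
    manifest, labeled = generate_dataset(
        setup.n_clips, "unused", seed=seed, base_params=base,
        param_ranges={"a_ED": (8.0, 12.0), "b_ED": (5.0, 8.5)},
        write_clips=False)
    sampled = [uniform_temporal_sample(lc.clip.pixels, RECOVERY_GRID.T)
               for lc in labeled]
    clips = np.stack([c.pixels for c in sampled])
    idxs = np.stack([c.source_frame_indices for c in sampled])
    efs = np.array([lc.ef for lc in labeled])
    splits = np.array([r.split for r in manifest.records])
    return {s: {"clips": clips[splits == s],
                "frame_indices": idxs[splits == s],
                "targets": efs[splits == s]}
            for s in ("train", "val", "test")}


def pretrain_recovery_encoder(data: dict, out_dir, seed: int,
                              setup: RecoverySetup):
    state = PretrainState(peak_lr=1e-3, warmup_init_lr=1e-4, batch_size=8,
                          mask_ratio=0.85, seed=seed)
    return run_pretraining(data["train"]["clips"], RECOVERY_GRID, RECOVERY_CFG,
                           state, out_dir, total_steps=setup.pretrain_steps)


def _labeled_subset(data: dict, n_labeled: int) -> dict:
    sub = dict(data)
    sub["train"] = {k: v[:n_labeled] for k, v in data["train"].items()}
    return sub


def _encode_all(checkpoint_path, data: dict, batch: int = 16) -> dict:
    """Frozen encoder representations (N, L_seq, d_model) per split.

    Representations are standardized per feature with train-split statistics
    (shared preprocessing for both probe arms).
    """
    sd, meta, _ = load_checkpoint(checkpoint_path)
    model = MaskedAutoencoder(CubeGridSpec.from_dict(meta["grid"]),
                              EncoderConfig.from_dict(meta["encoder"]))
    model.load_state_dict(sd)
    out = {}
    for split, d in data.items():
        reps = []
        for i in range(0, len(d["clips"]), batch):
            tok = model.embed(d["clips"][i:i + batch]) + Tensor(model.pos_enc)
            reps.append(model.encoder(tok).data.copy())
        out[split] = {"reps": np.concatenate(reps) if reps else np.zeros(0),
                      "frame_indices": d["frame_indices"],
                      "targets": d["targets"]}
    mu = out["train"]["reps"].mean(axis=(0, 1), keepdims=True)
    sd_ = out["train"]["reps"].std(axis=(0, 1), keepdims=True) + 1e-6
    for split in out:
        out[split]["reps"] = (out[split]["reps"] - mu) / sd_
    return out


class _FrozenHead(Module):
    """(STF-Net | mean pooling) + one linear map over frozen representations."""

    def __init__(self, grid: CubeGridSpec, use_stf: bool, stf_L: int, seed: int):
        rng = np.random.default_rng(seed)
        self.use_stf = use_stf
        self.stf = STFNet(grid, L=stf_L, seed=seed) if use_stf else None
        width = 2 * grid.d_model if use_stf else grid.d_model
        self.linear = Linear(width, 1, rng)

    def forward(self, reps: Tensor, frame_indices: np.ndarray) -> Tensor:
        feats = self.stf(reps, frame_indices) if self.use_stf else reps.mean(axis=1)
        return self.linear(feats).reshape(reps.shape[0])


def frozen_feature_contrast(feats: dict, setup: RecoverySetup,
                            fit_seed: int, epochs: int = 60,
                            lr: float = 1e-2) -> dict:
    """STF-Net + linear head vs mean pooling + linear head on a frozen encoder.

    `feats` comes from :func:`_encode_all`. Returns test metrics per arm;
    identical data, budget, and seed for both arms.
    """
    train = feats["train"]
    n = min(setup.n_labeled, len(train["targets"]))
    mean, std = train["targets"][:n].mean(), max(train["targets"][:n].std(), 1e-9)
    results = {}
    for name, use_stf in (("stf", True), ("mean_pool", False)):
        model = _FrozenHead(RECOVERY_GRID, use_stf, setup.stf_L, seed=fit_seed)
        opt = AdamW(model.parameters(), lr=lr, betas=(0.9, 0.98),
                    weight_decay=1e-3)
        rng = np.random.default_rng(fit_seed)
        for _ in range(epochs):
            order = rng.permutation(n)
            for i in range(0, n, setup.batch_size):
                idx = order[i:i + setup.batch_size]
                out = model(Tensor(train["reps"][idx]),
                            train["frame_indices"][idx])
                target = (train["targets"][idx] - mean) / std
                loss = ((out - Tensor(target.astype(np.float32))) ** 2.0).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
        test = feats["test"]
        preds = []
        for i in range(0, len(test["targets"]), setup.batch_size):
            out = model(Tensor(test["reps"][i:i + setup.batch_size]),
                        test["frame_indices"][i:i + setup.batch_size])
            preds.append(out.data * std + mean)
        pred = np.concatenate(preds)
        results[name] = regression_metrics(pred, test["targets"])
    return results


def run_recovery_contrasts(out_dir, seed: int = 0,
                           setup: RecoverySetup | None = None) -> dict:
    """Pre-train once, then run both downstream contrasts over the fit seeds.

    Contrast (i): end-to-end fine-tuning of a pre-trained encoder vs a
    random-init encoder, both with mean pooling and an MLP head.
    Contrast (ii): on the frozen pre-trained encoder, STF-Net + linear head
    vs mean pooling + linear head (mirrors the full-scale with/without-STF
    comparison at fixed representations).
    Returns per-arm test MAE lists plus win counts.
    """
    setup = setup or RecoverySetup()
    out_dir = Path(out_dir)
    data = build_recovery_data(seed, setup)
    pre = pretrain_recovery_encoder(data, out_dir / "pretrain", seed, setup)
    sub = _labeled_subset(data, setup.n_labeled)
    task = TaskSpec()

    maes: dict[str, list[float]] = {"pretrained_mean": [], "random_mean": [],
                                    "frozen_stf": [], "frozen_mean": []}
    feats = _encode_all(pre.checkpoint_path, data)
    for fit_seed in setup.seeds:
        for name, ckpt in (("pretrained_mean", pre.checkpoint_path),
                           ("random_mean", None)):
            opts = FitOptions(epochs=setup.finetune_epochs,
                              batch_size=setup.batch_size,
                              peak_lr=setup.finetune_lr, seed=fit_seed,
                              use_stf=False)
            res = finetune(ckpt, sub, task, opts, grid=RECOVERY_GRID,
                           cfg=RECOVERY_CFG)
            maes[name].append(float(res.report.metrics["mae"]))
        frozen = frozen_feature_contrast(feats, setup, fit_seed)
        maes["frozen_stf"].append(float(frozen["stf"]["mae"]))
        maes["frozen_mean"].append(float(frozen["mean_pool"]["mae"]))

    pre_wins = sum(p < r for p, r in zip(maes["pretrained_mean"],
                                         maes["random_mean"]))
    stf_wins = sum(s < m for s, m in zip(maes["frozen_stf"],
                                         maes["frozen_mean"]))
    return {"maes": maes, "pretrain_final_loss": pre.loss_history[-1],
            "pretrained_beats_random": pre_wins,
            "stf_beats_meanpool": stf_wins, "n_seeds": len(setup.seeds)}
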