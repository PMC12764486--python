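"""Downstream task heads, fine-tuning / linear-probing loops, and metrics.

Volumes are optionally trained in log space and always scored on the raw
scale after inverting the transform; inside the fit loops targets are
additionally standardized with training-split statistics for optimizer
stability, which is undone before any metric is computed.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
import numpy as np
from scipy import stats as sps
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from .checkpoint import load_checkpoint, save_checkpoint
from .errors import ContractError, DataError, ParameterError
from .mae_core import EncoderConfig, MaskedAutoencoder, PretrainState, lr_schedule
from .nn import AdamW, Linear, Module, Tensor, log_softmax, relu
from .stf_net import STFNet
from .tokenization import CubeGridSpec
from .video_io.clips import (read_video, resize_and_normalize,
                             uniform_temporal_sample)
from .video_io.manifest import DatasetManifest

__all__ = [
    "TaskSpec",
    "MetricsReport",
    "MLPHead",
    "attach_head",
    "transform_labels",
    "inverse_transform_labels",
    "regression_metrics",
    "classification_metrics",
    "clinical_metrics",
    "ef_threshold_labels",
    "bootstrap_ci",
    "DownstreamModel",
    "FitOptions",
    "finetune",
    "linear_probe",
    "load_clip_dataset",
    "evaluate_model",
]


# ---------------------------------------------------------------------
# task specification and label transforms
# ---------------------------------------------------------------------

@dataclass
class TaskSpec:
    kind: str = "regression"            # "regression" | "classification"
    target: str = "LV_EF"
    log_scale: bool = False
    ef_threshold: float | None = None   # fraction, e.g. 0.50 / 0.45
    n_classes: int = 2

    def __post_init__(self):
        if self.kind not in ("regression", "classification"):
            raise ParameterError(f"unknown task kind {self.kind!r}")
        if self.ef_threshold is not None and not 0.0 < self.ef_threshold < 1.0:
            raise ParameterError("ef_threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "target": self.target,
                "log_scale": self.log_scale, "ef_threshold": self.ef_threshold,
                "n_classes": self.n_classes}

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSpec":
        return cls(**d)


def transform_labels(values: np.ndarray, task: TaskSpec) -> np.ndarray:
    """ln(y) for log-scaled targets, identity otherwise."""
    values = np.asarray(values, dtype=np.float64)
    if task.log_scale:
        if np.any(values <= 0):
            raise DataError("log-scaled targets must be strictly positive")
        return np.log(values)
    return values.copy()


def inverse_transform_labels(values: np.ndarray, task: TaskSpec) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    return np.exp(values) if task.log_scale else values.copy()


def ef_threshold_labels(ef_values: np.ndarray, threshold: float) -> np.ndarray:
    """1 iff EF (in percent) / 100 >= threshold (preserved function positive)."""
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    ef = np.asarray(ef_values, dtype=np.float64)
    return (ef / 100.0 >= threshold).astype(np.int64)


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

def regression_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) < 2:
        raise ParameterError("pred/truth must be equal-length 1D arrays, n >= 2")
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        raise DataError("r^2 undefined: truth values are all equal")
    err = pred - truth
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err ** 2))
    ss_res = float(np.sum(err ** 2))
    return {"mae": mae, "mse": mse, "rmse": math.sqrt(mse),
            "r2": 1.0 - ss_res / ss_tot}


def classification_metrics(scores: np.ndarray, labels: np.ndarray,
                           n_classes: int) -> dict:
    """Row-stochastic probability scores -> accuracy / AUC / F1.

    Binary: AUC from the positive-class column, F1 on the positive class.
    Multi-class: macro one-vs-rest AUC and macro F1.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[1] != n_classes:
        raise ParameterError(f"scores must be (n, {n_classes})")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-5):
        raise ParameterError("probability rows must sum to 1")
    if len(np.unique(labels)) < 2:
        raise DataError("AUC undefined for single-class labels")
    preds = scores.argmax(axis=1)
    acc = float(accuracy_score(labels, preds))
    if n_classes == 2:
        auc = float(roc_auc_score(labels, scores[:, 1]))
        f1 = float(f1_score(labels, preds, pos_label=1))
    else:
        auc = float(roc_auc_score(labels, scores, multi_class="ovr",
                                  average="macro", labels=np.arange(n_classes)))
        f1 = float(f1_score(labels, preds, average="macro"))
    return {"accuracy": acc, "auc": auc, "f1": f1}


def clinical_metrics(pred_ef: np.ndarray, truth_ef: np.ndarray) -> dict:
    """Pearson correlation in percent, mean bias, and SD of the differences."""
    pred = np.asarray(pred_ef, dtype=np.float64)
    truth = np.asarray(truth_ef, dtype=np.float64)
    if pred.shape != truth.shape or len(pred) < 2:
        raise ParameterError("pred/truth must be equal-length arrays, n >= 2")
    if np.std(pred) == 0.0 or np.std(truth) == 0.0:
        raise DataError("Pearson correlation undefined for zero-variance input")
    cor = float(sps.pearsonr(pred, truth)[0]) * 100.0
    diff = pred - truth
    return {"cor": cor, "bias": float(np.mean(diff)),
            "std": float(np.std(diff, ddof=1))}


def bootstrap_ci(metric_fn, *arrays, n_boot: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Nonparametric percentile bootstrap over samples (rows of `arrays`)."""
    n = len(arrays[0])
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(metric_fn(*(a[idx] for a in arrays)))
        except (DataError, ValueError):
            continue  # degenerate resample (single class etc.)
    if not vals:
        raise DataError("all bootstrap resamples were degenerate")
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class MetricsReport:
    task: dict
    n: int
    metrics: dict[str, float]
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if "mse" in self.metrics and "rmse" in self.metrics:
            if abs(self.metrics["rmse"] - math.sqrt(self.metrics["mse"])) > 1e-9:
                raise ContractError("rmse != sqrt(mse)")

    def to_dict(self) -> dict:
        return {"task": self.task, "n": self.n, "metrics": self.metrics,
                "ci95": {k: list(v) for k, v in self.ci95.items()}}


# ---------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------

class MLPHead(Module):
    """Two linear layers with a ReLU between."""

    def __init__(self, in_width: int, out_dim: int, rng: np.random.Generator,
                 hidden: int | None = None):
        hidden = hidden or in_width
        self.fc1 = Linear(in_width, hidden, rng)
        self.fc2 = Linear(hidden, out_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(x)))


def attach_head(fused_width: int, task: TaskSpec, d_model: int,
                rng: np.random.Generator | None = None) -> MLPHead:
    """Build the task head; `fused_width` must be d_model or 2*d_model."""
    if fused_width not in (d_model, 2 * d_model):
        raise ContractError(
            f"fused width {fused_width} must be d_model ({d_model}) or 2*d_model")
    out_dim = 1 if task.kind == "regression" else task.n_classes
    return MLPHead(fused_width, out_dim, rng or np.random.default_rng(0))


class DownstreamModel(Module):
    """Cube embed + encoder + (STF-Net | mean pooling) + MLP head."""

    def __init__(self, grid: CubeGridSpec, cfg: EncoderConfig, task: TaskSpec,
                 use_stf: bool = True, stf_L: int = 1024, seed: int = 0):
        rng = np.random.default_rng(seed)
        mae = MaskedAutoencoder(grid, cfg, seed=seed)
        self.grid = grid
        self.cfg = cfg
        self.task = task
        self.use_stf = use_stf
        self.embed = mae.embed
        self.encoder = mae.encoder
        self.pos_enc = mae.pos_enc
        self.stf = STFNet(grid, L=stf_L, seed=seed + 1) if use_stf else None
        width = 2 * grid.d_model if use_stf else grid.d_model
        self.head = attach_head(width, task, grid.d_model, rng)
        # raw-scale inverse transform bookkeeping, set by the fit loop
        self.target_mean = 0.0
        self.target_std = 1.0

    def load_encoder_from(self, checkpoint_path) -> None:
        sd, meta, _ = load_checkpoint(checkpoint_path)
        if CubeGridSpec.from_dict(meta["grid"]) != self.grid:
            raise ContractError("checkpoint grid spec incompatible with data grid")
        own = dict(self.named_parameters())
        for name, arr in sd.items():
            if name.startswith(("embed.", "encoder.")):
                own[name].data = np.asarray(arr, dtype=np.float32).copy()

    def features(self, clips: np.ndarray, frame_indices: np.ndarray,
                 store_attention: bool = False) -> Tensor:
        tokens = self.embed(clips)
        tokens = tokens + Tensor(self.pos_enc)
        reps = self.encoder(tokens, store_attention=store_attention)
        if self.use_stf:
            return self.stf(reps, frame_indices)
        return reps.mean(axis=1)

    def forward(self, clips: np.ndarray, frame_indices: np.ndarray) -> Tensor:
        return self.head(self.features(clips, frame_indices))

    def predict(self, clips: np.ndarray, frame_indices: np.ndarray,
                batch_size: int = 16) -> np.ndarray:
        """Raw-scale predictions (regression) or probabilities (classification)."""
        outs = []
        for i in range(0, len(clips), batch_size):
            out = self.forward(clips[i:i + batch_size], frame_indices[i:i + batch_size])
            outs.append(out.data.copy())
        out = np.concatenate(outs, axis=0)
        if self.task.kind == "regression":
            raw = out[:, 0].astype(np.float64) * self.target_std + self.target_mean
            return inverse_transform_labels(raw, self.task)
        z = out - out.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------

def load_clip_dataset(manifest: DatasetManifest, grid: CubeGridSpec,
                      task: TaskSpec,
                      channel_stats: tuple | None = None) -> dict:
    """Decode every manifest clip to the grid's (T, 3, H, W) plus targets.

    Returns per-split dicts with 'clips', 'frame_indices', 'targets'.
    Classification targets for EF tasks are derived from the threshold.
    `channel_stats=(mean, std)` (3-vectors) optionally standardizes pixels
    per channel after the [0, 1] normalization (off by default).
    """
    out = {}
    for split in ("train", "val", "test"):
        sub = manifest.subset(split)
        clips, indices, targets = [], [], []
        for rec in sub.records:
            frames = read_video(rec.path)
            clip = uniform_temporal_sample(frames, grid.T, source_id=rec.path)
            clip = resize_and_normalize(clip, grid.H, grid.W)
            clips.append(clip.pixels)
            indices.append(clip.source_frame_indices)
            if task.kind == "classification" and task.ef_threshold is not None:
                targets.append(float(ef_threshold_labels(
                    np.array([rec.labels[task.target]]), task.ef_threshold)[0]))
            else:
                targets.append(rec.labels[task.target])
        stack = (np.stack(clips) if clips
                 else np.zeros((0, grid.T, 3, grid.H, grid.W), np.float32))
        if channel_stats is not None and len(stack):
            mean, std = (np.asarray(v, np.float32).reshape(1, 1, 3, 1, 1)
                         for v in channel_stats)
            stack = (stack - mean) / std
        out[split] = {
            "clips": stack,
            "frame_indices": np.asarray(indices, dtype=np.int64) if indices else np.zeros((0, grid.T), np.int64),
            "targets": np.asarray(targets, dtype=np.float64),
        }
    return out


# ---------------------------------------------------------------------
# fitting loops
# ---------------------------------------------------------------------

@dataclass
class FitOptions:
    epochs: int = 50
    batch_size: int = 16
    peak_lr: float = 1e-3
    warmup_fraction: float = 0.05
    betas: tuple[float, float] = (0.9, 0.98)
    weight_decay: float = 1e-3
    use_stf: bool = True
    stf_L: int = 1024
    seed: int = 0
    augment_flip_p: float = 0.0


@dataclass
class FitResult:
    model: DownstreamModel
    best_epoch: int
    val_losses: list[float]
    train_losses: list[float]
    report: MetricsReport


def _batch_loss(model: DownstreamModel, clips, idxs, targets_t: np.ndarray) -> Tensor:
    out = model.forward(clips, idxs)
    if model.task.kind == "regression":
        diff = out.reshape(out.shape[0]) - Tensor(targets_t.astype(np.float32))
        return (diff * diff).mean()
    logp = log_softmax(out, axis=-1)
    onehot = np.zeros(out.shape, dtype=np.float32)
    onehot[np.arange(len(targets_t)), targets_t.astype(np.int64)] = 1.0
    return -(Tensor(onehot) * logp).sum() * (1.0 / len(targets_t))


def _eval_loss(model: DownstreamModel, data: dict, targets_t: np.ndarray,
               batch_size: int) -> float:
    total, n = 0.0, len(targets_t)
    for i in range(0, n, batch_size):
        loss = _batch_loss(model, data["clips"][i:i + batch_size],
                           data["frame_indices"][i:i + batch_size],
                           targets_t[i:i + batch_size])
        total += float(loss.data) * len(targets_t[i:i + batch_size])
    return total / max(n, 1)


def _prepare_targets(model: DownstreamModel, task: TaskSpec, data: dict) -> dict:
    """Transformed (+standardized for regression) targets per split."""
    out = {}
    if task.kind == "regression":
        tr = transform_labels(data["train"]["targets"], task)
        mean, std = float(tr.mean()), float(tr.std())
        std = std if std > 1e-12 else 1.0
        model.target_mean, model.target_std = mean, std
        for split in ("train", "val", "test"):
            t = transform_labels(data[split]["targets"], task) if len(data[split]["targets"]) else np.zeros(0)
            out[split] = (t - mean) / std
    else:
        for split in ("train", "val", "test"):
            out[split] = data[split]["targets"].astype(np.int64)
    return out


def _fit(model: DownstreamModel, data: dict, task: TaskSpec, opts: FitOptions,
         trainable_params: list) -> FitResult:
    for split in ("train", "val"):
        if len(data[split]["targets"]) == 0:
            raise DataError(f"missing {split} split")
    targets = _prepare_targets(model, task, data)
    rng = np.random.default_rng(opts.seed)
    n = len(targets["train"])
    steps_per_epoch = int(math.ceil(n / opts.batch_size))
    total_steps = opts.epochs * steps_per_epoch
    sched = PretrainState(peak_lr=opts.peak_lr, warmup_fraction=opts.warmup_fraction,
                          warmup_init_lr=opts.peak_lr * 0.1, betas=opts.betas,
                          weight_decay=opts.weight_decay, seed=opts.seed)
    opt = AdamW(trainable_params, lr=opts.peak_lr, betas=opts.betas,
                weight_decay=opts.weight_decay)

    best_val = math.inf
    best_state: dict | None = None
    best_epoch = -1
    val_losses, train_losses = [], []
    step = 0
    for epoch in range(opts.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, opts.batch_size):
            idx = order[i:i + opts.batch_size]
            clips = data["train"]["clips"][idx]
            if opts.augment_flip_p > 0:
                flips = rng.random(len(idx)) < opts.augment_flip_p
                if flips.any():
                    clips = clips.copy()
                    clips[flips] = clips[flips][:, :, :, :, ::-1]
            opt.lr = lr_schedule(step, total_steps, sched)
            loss = _batch_loss(model, clips, data["train"]["frame_indices"][idx],
                               targets["train"][idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            step += 1
        train_losses.append(epoch_loss / n)
        val_loss = _eval_loss(model, data["val"], targets["val"], opts.batch_size)
        val_losses.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = copy.deepcopy(model.state_dict())

    model.load_state_dict(best_state)
    report = evaluate_model(model, data, task, seed=opts.seed)
    return FitResult(model=model, best_epoch=best_epoch, val_losses=val_losses,
                     train_losses=train_losses, report=report)


def evaluate_model(model: DownstreamModel, data: dict, task: TaskSpec,
                   seed: int = 0, n_boot: int = 200) -> MetricsReport:
    """Test-split metrics on the raw scale, with bootstrap CI95."""
    test = data["test"]
    if len(test["targets"]) == 0:
        raise DataError("missing test split")
    pred = model.predict(test["clips"], test["frame_indices"])
    truth = test["targets"]
    ci = {}
    if task.kind == "regression":
        metrics = regression_metrics(pred, truth)
        metrics.update(clinical_metrics(pred, truth))
        for key in ("mae", "r2"):
            fn = {"mae": lambda p, t: regression_metrics(p, t)["mae"],
                  "r2": lambda p, t: regression_metrics(p, t)["r2"]}[key]
            ci[key] = bootstrap_ci(fn, pred, truth, n_boot=n_boot, seed=seed)
    else:
        labels = truth.astype(np.int64)
        metrics = classification_metrics(pred, labels, task.n_classes)
        ci["accuracy"] = bootstrap_ci(
            lambda p, t: classification_metrics(p, t, task.n_classes)["accuracy"],
            pred, labels, n_boot=n_boot, seed=seed)
    return MetricsReport(task=task.to_dict(), n=len(truth), metrics=metrics, ci95=ci)


def finetune(checkpoint_path, manifest_or_data, task: TaskSpec,
             opts: FitOptions, grid: CubeGridSpec | None = None,
             cfg: EncoderConfig | None = None) -> FitResult:
    """End-to-end fine-tuning (encoder [+ STF-Net] + head).

    `checkpoint_path` may be None for a random-init encoder, in which case
    `grid` and `cfg` must be given. `manifest_or_data` is a DatasetManifest
    or a pre-decoded dataset dict from :func:`load_clip_dataset`.
    """
    if checkpoint_path is not None:
        _, meta, _ = load_checkpoint(checkpoint_path)
        grid = CubeGridSpec.from_dict(meta["grid"])
        cfg = EncoderConfig.from_dict(meta["encoder"])
    elif grid is None or cfg is None:
        raise ParameterError("random init requires explicit grid and encoder config")
    data = (manifest_or_data if isinstance(manifest_or_data, dict)
            else load_clip_dataset(manifest_or_data, grid, task))
    model = DownstreamModel(grid, cfg, task, use_stf=opts.use_stf,
                            stf_L=opts.stf_L, seed=opts.seed)
    if checkpoint_path is not None:
        model.load_encoder_from(checkpoint_path)
    return _fit(model, data, task, opts, model.parameters())


def linear_probe(checkpoint_path, manifest_or_data, task: TaskSpec,
                 opts: FitOptions) -> FitResult:
    """Train one linear map on frozen mean-pooled encoder representations."""
    _, meta, _ = load_checkpoint(checkpoint_path)
    grid = CubeGridSpec.from_dict(meta["grid"])
    cfg = EncoderConfig.from_dict(meta["encoder"])
    data = (manifest_or_data if isinstance(manifest_or_data, dict)
            else load_clip_dataset(manifest_or_data, grid, task))
    model = _ProbeModel(grid, cfg, task, seed=opts.seed)
    model.load_encoder_from(checkpoint_path)
    frozen = model.encoder_state()
    result = _fit(model, data, task, opts, [model.probe.weight, model.probe.bias])
    after = model.encoder_state()
    for k in frozen:
        if not np.array_equal(frozen[k], after[k]):
            raise ContractError(f"frozen encoder weight {k} changed during probing")
    return result


def save_finetuned(path, model: DownstreamModel, extra_meta: dict | None = None) -> None:
    meta = {"kind": "finetune", "grid": model.grid.to_dict(),
            "encoder": model.cfg.to_dict(), "task": model.task.to_dict(),
            "use_stf": model.use_stf,
            "target_mean": model.target_mean, "target_std": model.target_std}
    if model.use_stf:
        meta["stf_L"] = model.stf.joint.pool.V.weight.shape[1]
    if extra_meta:
        meta.update(extra_meta)
    save_checkpoint(path, model.state_dict(), meta)


def load_finetuned(path) -> DownstreamModel:
    sd, meta, _ = load_checkpoint(path)
    grid = CubeGridSpec.from_dict(meta["grid"])
    cfg = EncoderConfig.from_dict(meta["encoder"])
    task = TaskSpec.from_dict(meta["task"])
    if meta.get("kind") == "probe":
        model = _ProbeModel(grid, cfg, task)
    else:
        model = DownstreamModel(grid, cfg, task, use_stf=bool(meta["use_stf"]),
                                stf_L=int(meta.get("stf_L", 1024)))
    model.load_state_dict(sd)
    model.target_mean = float(meta["target_mean"])
    model.target_std = float(meta["target_std"])
    return model


class _ProbeModel(DownstreamModel):
    """Frozen encoder + single linear layer on mean-pooled tokens."""

    def __init__(self, grid: CubeGridSpec, cfg: EncoderConfig, task: TaskSpec,
                 seed: int = 0):
        super().__init__(grid, cfg, task, use_stf=False, seed=seed)
        rng = np.random.default_rng(seed + 17)
        out_dim = 1 if task.kind == "regression" else task.n_classes
        self.probe = Linear(grid.d_model, out_dim, rng)

    def forward(self, clips: np.ndarray, frame_indices: np.ndarray) -> Tensor:
        feats = self.features(clips, frame_indices)
        return self.probe(Tensor(feats.data.copy()))  # gradient-isolated encoder

    def encoder_state(self) -> dict:
        return {k: v for k, v in self.state_dict().items()
                if k.startswith(("embed.", "encoder."))}
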