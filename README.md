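# echovid

Self-supervised masked video auto-encoding and dual-pathway spatio-temporal
fusion for echocardiogram-style clip analysis — implemented end to end on
NumPy (a small built-in autodiff engine), so everything runs on one CPU with
no deep-learning framework.

## What's inside

| module | role |
| --- | --- |
| `echovid.video_io` | uncompressed-AVI read/write, uniform temporal sampling, bilinear resize, seeded flips, CSV label manifests |
| `echovid.synthetic_echo` | beating-chamber ultrasound phantoms with exact EF/ESV/EDV labels (`EF = 100·(1−(1−c)³)` from the contraction `c`) |
| `echovid.tokenization` | space-time cube embedding, seeded token masks (`⌊ρ·L_seq⌋`), fixed 3D sinusoidal positional encodings |
| `echovid.mae_core` | asymmetric masked auto-encoder (visible-token encoder, shallow full-grid decoder), masked-cube MSE, warmup+cosine LR schedule, pre-training loop |
| `echovid.stf_net` | joint (3D res-block) and disjoint (2D res-block + learnable-pooling conv + sparse temporal encodings) fusion pathways, gated-attention pooling, 2·d_model fused output |
| `echovid.tasks_eval` | MLP task heads, fine-tuning / linear probing with best-val-checkpoint selection, log-scaled volume transforms, regression / classification / clinical metrics with bootstrap CIs |
| `echovid.interpret` | attention rollout, per-row 3D saliency with bilinear upsampling, deterministic PNG/AVI overlays |
| `echovid.config` / `echovid.cli` | YAML configs with `full` (16×3×224×224, d_model 768, depths 12/4, ρ=0.85) and `tiny` (CPU-sized) profiles; `synth / pretrain / finetune / probe / eval / explain` subcommands |
| `echovid.nn` | reverse-mode autodiff over NumPy: transformer blocks, group/layer norm, 2D/3D convs, AdamW |

No external data is required: the phantom generator produces labeled AVI
clips and manifests for every stage.

## CLI walkthrough (tiny profile)

```bash
echovid --profile tiny synth --n 60 --out out/phantom
echovid --profile tiny pretrain --manifest out/phantom/manifest.csv
echovid --profile tiny finetune --manifest out/phantom/manifest.csv \
    --checkpoint out/checkpoints/pretrain_checkpoint.npz
echovid --profile tiny eval --manifest out/phantom/manifest.csv \
    --checkpoint out/checkpoints/finetune_model.npz
echovid --profile tiny explain --checkpoint out/checkpoints/finetune_model.npz \
    --clip out/phantom/clip_00000.avi --token center
```

`--config experiment.yaml` overrides any profile default (grid strides,
mask ratio, optimizer settings, task spec, seeds); `--stf off` reproduces
the mean-pooling ablation, `probe` the frozen-encoder linear probe.

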