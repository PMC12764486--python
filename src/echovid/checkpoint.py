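"""Single-file (.npz) checkpoints: weights + grid/encoder config + seeds."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(path, state: dict, meta: dict,
                    optimizer_state: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param/{k}": v for k, v in state.items()}
    if optimizer_state:
        for k, v in optimizer_state.items():
            arrays[f"opt/{k}"] = np.asarray(v)
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> tuple[dict, dict, dict]:
    """Returns (state_dict, meta, optimizer_state)."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
        opt = {k[len("opt/"):]: data[k] for k in data.files if k.startswith("opt/")}
    return state, meta, opt
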