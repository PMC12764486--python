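"""CSV label manifests: `path,split,label_name,label_value` rows.

One clip may carry several labels (one row per label). Splits are
train/val/test.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from ..errors import DataError

__all__ = ["ManifestRecord", "DatasetManifest", "VALID_SPLITS"]

VALID_SPLITS = ("train", "val", "test")


@dataclass
class ManifestRecord:
    path: str
    split: str
    labels: dict[str, float] = field(default_factory=dict)


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if rec.split not in VALID_SPLITS:
                raise DataError(f"invalid split tag {rec.split!r} for {rec.path}")
            if rec.path in seen:
                raise DataError(f"duplicate manifest path {rec.path}")
            seen.add(rec.path)

    def subset(self, split: str) -> "DatasetManifest":
        if split not in VALID_SPLITS:
            raise DataError(f"invalid split tag {split!r}")
        return DatasetManifest([r for r in self.records if r.split == split])

    def __len__(self) -> int:
        return len(self.records)

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "split", "label_name", "label_value"])
            for rec in self.records:
                if not rec.labels:
                    writer.writerow([rec.path, rec.split, "", ""])
                for name, value in rec.labels.items():
                    writer.writerow([rec.path, rec.split, name, repr(float(value))])

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        path = Path(path)
        by_path: dict[str, ManifestRecord] = {}
        order: list[str] = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"path", "split", "label_name", "label_value"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise DataError(f"{path}: manifest header must contain {sorted(required)}")
            for row in reader:
                key = row["path"]
                if key not in by_path:
                    by_path[key] = ManifestRecord(path=key, split=row["split"], labels={})
                    order.append(key)
                rec = by_path[key]
                if rec.split != row["split"]:
                    raise DataError(f"{path}: conflicting splits for {key}")
                name = row["label_name"]
                if name:
                    if name in rec.labels:
                        raise DataError(f"{path}: duplicate label {name!r} for {key}")
                    rec.labels[name] = float(row["label_value"])
        return cls([by_path[k] for k in order])
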