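"""File I/O: PNG masks and probability maps, cohort directories, reports.

Binary masks are 8-bit single-channel PNG with {0, 255} (any nonzero pixel
reads back as 1). Probability maps are 16-bit single-channel PNG with
value = round(p * 65535). A cohort directory holds images/, lesion_masks/,
network_masks/ and metadata.csv (columns image, lesion_id, diagnosis).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import LesionRecord

__all__ = [
    "read_mask", "write_mask", "read_prob_map", "write_prob_map",
    "write_cohort", "read_cohort", "write_json",
]

_PROB_SCALE = 65535


def write_mask(path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask).astype(bool) * np.uint8(255))
    iio.imwrite(Path(path), arr, extension=".png")


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_prob_map(path, prob_map: np.ndarray) -> None:
    p = np.asarray(prob_map, dtype=float)
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    iio.imwrite(Path(path), np.round(p * _PROB_SCALE).astype(np.uint16),
                extension=".png")


def read_prob_map(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(float) / _PROB_SCALE


def write_cohort(records: list[LesionRecord], metadata: pd.DataFrame,
                 out_dir) -> None:
    out = Path(out_dir)
    for sub in ("images", "lesion_masks", "network_masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for rec in records:
        iio.imwrite(out / "images" / f"{rec.image_id}.png", rec.image,
                    extension=".png")
        write_mask(out / "lesion_masks" / f"{rec.image_id}.png",
                   rec.lesion_mask)
        write_mask(out / "network_masks" / f"{rec.image_id}.png",
                   rec.network_mask)
    metadata.to_csv(out / "metadata.csv", index=False)


def read_cohort(in_dir) -> tuple[list[LesionRecord], pd.DataFrame]:
    src = Path(in_dir)
    csv = src / "metadata.csv"
    if not csv.exists():
        raise FileNotFoundError(f"missing metadata file: {csv}")
    metadata = pd.read_csv(csv)
    for col in ("image", "lesion_id", "diagnosis"):
        if col not in metadata.columns:
            raise ValueError(f"metadata.csv lacks required column {col!r}")
    records = []
    for row in metadata.itertuples(index=False):
        image_id = row.image
        records.append(LesionRecord(
            image_id=image_id,
            lesion_id=str(row.lesion_id),
            image=iio.imread(src / "images" / f"{image_id}.png"),
            lesion_mask=read_mask(src / "lesion_masks" / f"{image_id}.png"),
            network_mask=read_mask(src / "network_masks" / f"{image_id}.png"),
            label=1 if row.diagnosis == "MEL" else 0,
        ))
    return records, metadata


def write_json(path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
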