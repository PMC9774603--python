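"""Image loading and preprocessing for manifest-driven training/evaluation."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .pspi import FrameRecord, cluster_level

__all__ = ["load_image", "preprocess", "read_manifest", "load_dataset"]


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def preprocess(image: np.ndarray, size: int) -> np.ndarray:
    """uint8 (H, W, 3) -> float64 (3, size, size) in [-1, 1]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    if image.shape[:2] != (size, size):
        im = Image.fromarray(image.astype(np.uint8)).resize((size, size), Image.BILINEAR)
        image = np.asarray(im)
    x = image.astype(np.float64) / 255.0
    return (x - 0.5).transpose(2, 0, 1) * 2.0


def read_manifest(path: str | Path) -> list[FrameRecord]:
    """Read a split manifest (CSV with frame_id, image_path, pspi columns)."""
    df = pd.read_csv(path)
    required = {"frame_id", "image_path", "pspi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        pspi = int(row["pspi"])
        level = int(row["clustered_level"]) if "clustered_level" in df.columns else cluster_level(pspi)
        records.append(
            FrameRecord(
                frame_id=str(row["frame_id"]),
                image_path=str(row["image_path"]),
                pspi=pspi,
                clustered_level=level,
            )
        )
    return records


def load_dataset(records: Sequence[FrameRecord], size: int,
                 root: str | Path | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Load all images referenced by the records.

    Returns (X, y): X is (N, 3, size, size) preprocessed, y the clustered
    levels.  ``root`` resolves relative image paths.
    """
    xs, ys = [], []
    for r in records:
        if r.image_path is None:
            raise ValueError(f"record {r.frame_id!r} has no image_path")
        path = Path(r.image_path)
        if root is not None and not path.is_absolute():
            path = Path(root) / path
        xs.append(preprocess(load_image(path), size))
        if r.clustered_level is None:
            raise ValueError(f"record {r.frame_id!r} has no clustered_level")
        ys.append(r.clustered_level)
    return np.stack(xs), np.asarray(ys, dtype=int)
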