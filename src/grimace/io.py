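"""Metadata table and image I/O.

The metadata CSV has one row per image with the declared schema below;
unknown columns are preserved on round-trip.  Images are PNG/JPEG
grayscale or RGB files referenced by ``image_path`` relative to a root
directory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "REQUIRED_COLUMNS",
    "read_metadata",
    "write_metadata",
    "load_images",
    "save_images",
]

REQUIRED_COLUMNS = (
    "image_path",
    "animal_id",
    "sex",
    "treatment",
    "time_label",
    "binary_label",
)


def read_metadata(path) -> pd.DataFrame:
    """Read a metadata CSV, checking the required column schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"metadata {path} is missing required column(s): {missing}")
    return df


def write_metadata(table: pd.DataFrame, path) -> None:
    """Write a metadata table; round-trips through :func:`read_metadata`."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metadata table is missing column(s): {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def load_images(table: pd.DataFrame, root) -> list[np.ndarray]:
    """Load every ``image_path`` in the table, relative to ``root``."""
    root = Path(root)
    images = []
    for p in table["image_path"]:
        f = root / p
        if not f.exists():
            raise FileNotFoundError(f"image file not found: {f}")
        images.append(np.asarray(Image.open(f)))
    return images


def save_images(images, paths, root) -> None:
    root = Path(root)
    for img, p in zip(images, paths, strict=True):
        out = root / p
        out.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(np.asarray(img)).save(out)
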