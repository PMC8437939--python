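"""Image and manifest input/output (PNG/TIFF, CSV)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as a 2-D array (grayscale; RGB is averaged)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return np.asarray(arr)


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write a binary or grayscale image as 8-bit PNG/TIFF."""
    img = np.asarray(img)
    if img.dtype == bool:
        img = img.astype(np.uint8) * 255
    elif img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), img)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a corpus manifest CSV; image paths are kept relative to it."""
    df = pd.read_csv(path)
    df.attrs["root"] = str(Path(path).parent)
    return df
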