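"""Image I/O: 8/16-bit grayscale PNG and TIFF, normalised to [0, 1]."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InputError


def read_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF and rescale to [0, 1] by max code value."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"image not found: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:  # RGB(A): average colour channels
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr = arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def write_image(path, pixels: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    path = Path(path)
    arr = np.asarray(pixels, dtype=float)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise InputError("image intensities must lie in [0, 1]")
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)
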