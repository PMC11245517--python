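"""Reading radiograph images (PNG, optionally DICOM) and PNG label masks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["load_image", "load_mask", "load_sample"]

_DICOM_SUFFIXES = {".dcm", ".dicom"}


def load_image(path: str | Path) -> np.ndarray:
    """Grayscale intensity array scaled to [0, 1] (8/16-bit PNG or DICOM)."""
    path = Path(path)
    if path.suffix.lower() in _DICOM_SUFFIXES:
        import pydicom

        arr = pydicom.dcmread(path).pixel_array.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim == 3:  # collapse accidental RGB to luminance
        arr = arr.mean(axis=2)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype in (np.uint16, np.int32):
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def load_mask(path: str | Path) -> np.ndarray:
    """Integer label mask from a PNG file."""
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"mask {path} is not a single-channel label image")
    return arr.astype(np.uint8)


def load_sample(record) -> tuple[np.ndarray, np.ndarray]:
    """(image, mask) arrays for a cohort record."""
    return load_image(record.image_path), load_mask(record.mask_path)
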