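"""Image I/O and per-image intensity normalization.

2D images travel as 16-bit PNG; 3D volumes as NIfTI-1 through nibabel, the
affine passed through untouched.  Before entering the models, each image is
scaled to [0,1] — min–max for 2D, robust 1st/99th-percentile scaling (then
clipping) for 3D volumes, where extreme voxels would otherwise dominate the
range.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = ["load_image", "save_image", "minmax_scale", "percentile_scale", "normalize"]

_PNG_MAX = 65535.0


def load_image(path) -> np.ndarray:
    """Read a PNG (2D, rescaled to [0,1]) or NIfTI (3D, raw values)."""
    path = Path(path)
    if path.suffix == ".png":
        arr = iio.imread(path).astype(np.float64)
        return arr / _PNG_MAX
    if path.name.endswith((".nii", ".nii.gz")):
        return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    raise ValueError(f"unsupported image format: {path}")


def save_image(image: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a [0,1] 2D image as 16-bit PNG or a 3D volume as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".png":
        if image.ndim != 2:
            raise ValueError(f"PNG output requires a 2D image, got shape {image.shape}")
        arr = np.clip(image, 0.0, 1.0)
        iio.imwrite(path, (arr * _PNG_MAX).round().astype(np.uint16))
        return
    if path.name.endswith((".nii", ".nii.gz")):
        aff = np.eye(4) if affine is None else affine
        nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32), aff), str(path))
        return
    raise ValueError(f"unsupported image format: {path}")


def minmax_scale(image: np.ndarray) -> np.ndarray:
    """Scale to [0,1] by the image's own min and max (constant image -> 0)."""
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return np.zeros_like(image, dtype=np.float64)
    return (image - lo) / (hi - lo)


def percentile_scale(image: np.ndarray, p_low: float = 1.0, p_high: float = 99.0) -> np.ndarray:
    """Scale by the (p_low, p_high) percentiles and clip to [0,1]."""
    lo, hi = np.percentile(image, [p_low, p_high])
    if hi <= lo:
        return np.zeros_like(image, dtype=np.float64)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def normalize(image: np.ndarray, mode: str = "auto") -> np.ndarray:
    """Per-image normalization: `minmax` (2D default) or `percentile` (3D)."""
    if mode == "auto":
        mode = "minmax" if image.ndim == 2 else "percentile"
    if mode == "minmax":
        return minmax_scale(image)
    if mode == "percentile":
        return percentile_scale(image)
    if mode == "none":
        return np.asarray(image, dtype=np.float64)
    raise ValueError(f"unknown normalization mode {mode!r}")
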