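"""Image and mask I/O: 8/16-bit PNG/TIFF, lossless integer roundtrips."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]

_SUFFIXES = {".png", ".tif", ".tiff"}


def _check_path(path: Path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in _SUFFIXES:
        raise ValueError(f"unsupported image format {path.suffix!r} "
                         f"(supported: {sorted(_SUFFIXES)})")
    return path


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF into a float array in [0, 1] (HxW or HxWx3)."""
    path = _check_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(f"unsupported dtype {arr.dtype} in {path}")
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")
    return arr.astype(np.float64) / scale


def write_image(path, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write a float image in [0, 1]; integers quantized to ``bit_depth``."""
    path = _check_path(path)
    image = np.asarray(image, dtype=np.float64)
    if image.min() < -1e-9 or image.max() > 1 + 1e-9:
        raise ValueError("image values must lie in [0, 1]")
    if bit_depth == 8:
        data = np.round(np.clip(image, 0, 1) * 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(np.clip(image, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(path, data)


def read_mask(path) -> np.ndarray:
    """Read a single-channel {0, 255} PNG mask into a {0, 1} uint8 grid."""
    path = _check_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > 0).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    path = _check_path(path)
    mask = np.asarray(mask)
    iio.imwrite(path, ((mask > 0) * np.uint8(255)))
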