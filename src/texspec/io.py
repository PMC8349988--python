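"""Image and config I/O.

Images are handled as linear luminance in [0, 1] (no gamma transform is
applied; display linearization is assumed upstream). Color inputs are
collapsed with Rec. 709 luma weights; non-square or non-power-of-two inputs
are center-cropped to the largest valid square with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

__all__ = ["read_image", "write_image", "write_provenance"]

log = logging.getLogger(__name__)

_REC709 = np.array([0.2126, 0.7152, 0.0722])


def _largest_pow2_at_most(n: int) -> int:
    return 1 << (n.bit_length() - 1)


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale (or color, luma-converted) image as luminance in [0, 1].

    Integer images are scaled by their dtype maximum (255 -> 1.0 for 8-bit,
    65535 -> 1.0 for 16-bit); float images are assumed already in [0, 1].
    The result is center-cropped to the largest power-of-two square.
    """
    raw = np.asarray(iio.imread(path))
    src_dtype = raw.dtype
    if raw.ndim == 3:
        raw = raw[..., :3] @ _REC709
    if raw.ndim != 2 or min(raw.shape) < 1:
        raise ValueError(f"{path}: expected a 2D image, got shape {raw.shape}")
    arr = np.asarray(raw, dtype=float)
    if np.issubdtype(src_dtype, np.integer):
        arr = arr / np.iinfo(src_dtype).max
    h, w = arr.shape
    side = _largest_pow2_at_most(min(h, w))
    if (h, w) != (side, side):
        log.warning("%s: center-cropping %dx%d to %dx%d", path, h, w, side, side)
        top = (h - side) // 2
        left = (w - side) // 2
        arr = arr[top : top + side, left : left + side]
    return arr


def write_image(image: np.ndarray, path: str | Path, bit_depth: int = 16) -> None:
    """Write a [0, 1] luminance image as 8- or 16-bit grayscale PNG/TIFF.

    Values are mapped linearly (1.0 -> dtype max); out-of-range pixels are
    clipped and counted in a logged warning.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    clipped = int(np.count_nonzero((image < 0.0) | (image > 1.0)))
    if clipped:
        log.warning("%s: clipped %d out-of-range pixels", path, clipped)
    image = np.clip(image, 0.0, 1.0)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    scale = np.iinfo(dtype).max
    iio.imwrite(path, np.round(image * scale).astype(dtype))


def write_provenance(path: str | Path, record: dict) -> None:
    """Dump a run's configuration echo (command, parameters, seed) as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=True)
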