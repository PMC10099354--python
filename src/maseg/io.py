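"""Image and mask readers/writers.

Masks follow the annotation convention of the source data: microaneurysm
pixels are black (0) and background is white (255); in memory a mask is a
boolean array with ``True`` marking a microaneurysm pixel.  Reading then
writing a binary mask is lossless.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

#: 8-bit value written for a microaneurysm pixel.
MA_VALUE = 0
#: 8-bit value written for a background pixel.
BACKGROUND_VALUE = 255
#: Intensities at or below this midpoint are read as microaneurysm.
BINARIZE_TOL = 127


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an (H, W, 3) uint8 RGB array.

    Grayscale images are promoted to three identical channels; an alpha
    channel is dropped.  JPEG input is accepted with a warning, since its
    lossy compression perturbs pixel values.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        logger.warning("reading lossy JPEG %s; pixel values are approximate", path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) uint8 RGB array as an image file (PNG recommended)."""
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask image into a boolean array (True = microaneurysm).

    Any pixel at or below the intensity midpoint counts as microaneurysm.
    A warning with an intensity summary is emitted when the file does not
    look binary (many intermediate values).
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    extreme = (arr <= 10) | (arr >= 245)
    frac_mid = 1.0 - extreme.mean()
    if frac_mid > 0.05:
        hist, _ = np.histogram(arr, bins=8, range=(0, 256))
        logger.warning(
            "mask %s does not look binary: %.1f%% of pixels have intermediate "
            "intensity (8-bin histogram: %s)", path, 100 * frac_mid, hist.tolist())
    return arr <= BINARIZE_TOL


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit image: MA = black 0, background = white 255."""
    mask = np.asarray(mask, dtype=bool)
    out = np.where(mask, MA_VALUE, BACKGROUND_VALUE).astype(np.uint8)
    iio.imwrite(Path(path), out)
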