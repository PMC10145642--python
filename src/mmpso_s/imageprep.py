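"""Image reading/writing and pre-processing.

The thresholding pipeline operates on a pre-processed grayscale image
``Ipre``: the RGB input is converted to luminance (ITU-R BT.601 weights)
and contrast-enhanced with CLAHE (contrast-limited adaptive histogram
equalization).  All downstream intensity computations — the histogram,
the threshold search, the segmentation maps and the superpixel cluster
refinement — consume this ``Ipre``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import exposure

from .exceptions import ConfigError, ImageIOError, InvalidInputError

__all__ = [
    "to_grayscale",
    "enhance_contrast",
    "preprocess",
    "read_image",
    "write_image",
    "write_mask",
]

# ITU-R BT.601 luma weights for R, G, B.
_BT601 = np.array([0.299, 0.587, 0.114])


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit grayscale.

    Uses the BT.601 luminance weights 0.299/0.587/0.114, rounds to the
    nearest integer and clamps to [0, 255].  Idempotent on inputs whose
    three channels are equal.

    Parameters
    ----------
    img : ndarray of shape (H, W, 3)
        Integer intensities in [0, 255].

    Returns
    -------
    ndarray of shape (H, W), dtype uint8
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise InvalidInputError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
    if img.size == 0:
        raise InvalidInputError("empty image")
    gray = img.astype(np.float64) @ _BT601
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def enhance_contrast(
    img: np.ndarray,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Apply CLAHE to a grayscale image.

    Parameters
    ----------
    img : ndarray of shape (H, W)
        8-bit grayscale image.
    clip_limit : float
        Normalized clipping ceiling for the per-tile histogram (fraction
        of tile pixel count); must be positive.
    tile_grid : (rows, cols)
        Number of contextual tiles along each axis; edge tiles may be
        smaller when the grid does not divide the image exactly.

    Returns
    -------
    ndarray of shape (H, W), dtype uint8, values in [0, 255].
    """
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise InvalidInputError(f"expected a non-empty H x W grayscale image, got shape {img.shape}")
    if clip_limit <= 0:
        raise ConfigError(f"clip_limit must be > 0, got {clip_limit}")
    rows, cols = tile_grid
    if rows < 1 or cols < 1:
        raise ConfigError(f"tile_grid entries must be >= 1, got {tile_grid}")
    # A constant image has no gradients to equalize; CLAHE maps it to an
    # (arbitrary) constant, which we pin to the input value.
    if img.min() == img.max():
        return img.astype(np.uint8, copy=True)
    kernel = (max(1, img.shape[0] // rows), max(1, img.shape[1] // cols))
    out = exposure.equalize_adapthist(img.astype(np.uint8), kernel_size=kernel, clip_limit=clip_limit)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def preprocess(
    img: np.ndarray,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Full pre-processing chain: grayscale conversion followed by CLAHE."""
    return enhance_contrast(to_grayscale(img), clip_limit=clip_limit, tile_grid=tile_grid)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG or TIFF image as an 8-bit RGB array.

    Grayscale files are replicated across three channels, alpha channels
    are dropped, and 16-bit inputs are rescaled to 8-bit (with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"cannot read image: no such file: {path}")
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:  # pragma: no cover - backend specific
        raise ImageIOError(f"failed to read image {path}: {exc}") from exc
    if arr.dtype == np.uint16:
        warnings.warn(f"{path}: 16-bit image rescaled to 8-bit", UserWarning, stacklevel=2)
        arr = (arr.astype(np.float64) / 65535.0 * 255.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ImageIOError(f"unsupported bit depth {arr.dtype} in {path}; expected 8- or 16-bit")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageIOError(f"unsupported image layout {arr.shape} in {path}")
    return arr


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write an 8-bit image (grayscale or RGB) as PNG/TIFF."""
    path = Path(path)
    try:
        iio.imwrite(path, np.asarray(img, dtype=np.uint8))
    except Exception as exc:  # pragma: no cover
        raise ImageIOError(f"failed to write image {path}: {exc}") from exc


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG with values {0, 255}."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InvalidInputError(f"mask must be 2-D, got shape {mask.shape}")
    write_image(path, (mask.astype(bool) * np.uint8(255)))
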