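"""Image I/O and preprocessing: Gaussian smoothing and cropping.

Images are handled as 2-D float arrays normalized to [0, 1], row/column
indexed with unit pixel spacing.  The standard preprocessing for capture
images is a 5x5 Gaussian filter with standard deviation 3 px followed by a
fixed crop that removes the black background around the finger (e.g.
352x288 captures cropped to 221x83).
"""

from __future__ import annotations

from collections import namedtuple

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import correlate1d

__all__ = ["CropBox", "load_image", "save_image", "gaussian_kernel1d",
           "gaussian_smooth", "crop"]

#: Crop window: top-left corner (row, col) and extents (height, width).
CropBox = namedtuple("CropBox", ["row", "col", "height", "width"])

_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale or RGB image as floats in [0, 1].

    RGB is converted by the ITU-R 601 luminance weights.
    """
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.size == 0:
        raise OSError(f"empty image file {path!r}")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
        scale = 255.0 if arr.max() <= 255.0 else 65535.0
    elif arr.ndim == 2:
        scale = 65535.0 if arr.dtype.itemsize > 1 else 255.0
    else:
        raise ValueError(f"{path!r}: expected a 2-D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating) and arr.max() <= 1.0:
        scale = 1.0
    return arr.astype(float) / scale


def save_image(path, img: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG/PGM/BMP/TIFF by extension."""
    out = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (out * 255.0 + 0.5).astype(np.uint8))


def gaussian_kernel1d(size: int = 5, sigma: float = 3.0) -> np.ndarray:
    """Normalized truncated Gaussian kernel of odd length ``size``."""
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    z = np.arange(size) - size // 2
    k = np.exp(-(z**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_smooth(img: np.ndarray, size: int = 5, sigma: float = 3.0) -> np.ndarray:
    """Separable convolution with a normalized truncated Gaussian.

    Reflect padding at the borders so the frame does not acquire dark edges
    that the curvature stage would mistake for vessels.
    """
    k = gaussian_kernel1d(size, sigma)
    out = correlate1d(np.asarray(img, dtype=float), k, axis=0, mode="reflect")
    return correlate1d(out, k, axis=1, mode="reflect")


def crop(img: np.ndarray, box: CropBox) -> np.ndarray:
    """Extract the exact sub-grid given by ``box``; must lie within bounds."""
    box = CropBox(*box)
    h, w = img.shape
    if box.height <= 0 or box.width <= 0:
        raise ValueError(f"crop box must have positive extents, got {box}")
    if box.row < 0 or box.col < 0 or box.row + box.height > h or box.col + box.width > w:
        raise ValueError(f"crop box {box} exceeds image bounds {h}x{w}")
    return img[box.row:box.row + box.height, box.col:box.col + box.width].copy()
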