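"""Image containers, TIFF I/O, 8-bit conversion, and intensity histograms.

Conventions used throughout the package
---------------------------------------
* A *gray image* is a 2-D ``numpy.ndarray`` of dtype ``uint8`` (values 0–255),
  indexed ``[row, col]``.
* A *binary mask* is a 2-D boolean array of the same shape as the image it
  was derived from; ``True`` is foreground (signal, rendered white).
* Intensity arithmetic rounds half up (``floor(x + 0.5)``) so results are
  bit-identical across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import DimensionError, FormatError

__all__ = [
    "GRAY_LEVELS",
    "IntensityHistogram",
    "round_half_up",
    "as_gray8",
    "to_gray8",
    "read_gray_tiff",
    "write_gray_tiff",
    "compute_histogram",
]

GRAY_LEVELS = 256

#: ITU-R BT.601 luminance weights used to collapse RGB to gray.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round with ties away from zero toward +inf (0.5 -> 1), elementwise."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def as_gray8(image: np.ndarray) -> np.ndarray:
    """Validate that *image* is a 2-D uint8 gray image and return it.

    Raises
    ------
    DimensionError
        If the array is not 2-D or has a zero-length axis.
    FormatError
        If the dtype is not ``uint8``.
    """
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise DimensionError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"expected uint8 gray image, got dtype {arr.dtype}")
    return arr


def to_gray8(image: np.ndarray) -> np.ndarray:
    """Convert any non-negative integer image to 8-bit by min–max rescaling.

    The full observed range ``[min, max]`` is mapped linearly onto
    ``[0, 255]`` with round-half-up.  A constant image maps to all zeros:
    a featureless field should binarize to empty foreground downstream.
    Images already spanning [0, 255] pass through unchanged (idempotence).
    """
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise DimensionError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.signedinteger) and arr.min() < 0:
        raise FormatError("negative intensities have no 8-bit mapping")
    if np.issubdtype(arr.dtype, np.floating) and arr.min() < 0:
        raise FormatError("negative intensities have no 8-bit mapping")
    lo = float(arr.min())
    hi = float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    scaled = round_half_up((arr.astype(np.float64) - lo) * 255.0 / (hi - lo))
    return scaled.astype(np.uint8)


def read_gray_tiff(path) -> np.ndarray:
    """Read a TIFF as an 8-bit gray image.

    Accepted layouts: 8-bit gray (returned bit-exactly), 16-bit gray
    (min–max rescaled to 8 bit), and 8-bit RGB/RGBA (collapsed with the
    ITU-R BT.601 luminance weights 0.299 R + 0.587 G + 0.114 B, rounded).

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FormatError
        For bit depths or layouts with no lossless mapping (floats, etc.).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such image file: {p}")
    arr = tifffile.imread(str(p))
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        if arr.dtype != np.uint8:
            raise FormatError(f"only 8-bit RGB TIFFs are supported, got {arr.dtype}")
        luma = round_half_up(arr[..., :3].astype(np.float64) @ _LUMA_WEIGHTS)
        return luma.astype(np.uint8)
    if arr.ndim != 2:
        raise FormatError(f"expected a single 2-D plane, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return to_gray8(arr)
    raise FormatError(f"unsupported TIFF sample format: {arr.dtype}")


def write_gray_tiff(path, image: np.ndarray) -> None:
    """Write an 8-bit gray image as an uncompressed single-plane TIFF."""
    tifffile.imwrite(str(path), as_gray8(image))


@dataclass(frozen=True)
class IntensityHistogram:
    """256-bin intensity histogram; the sole input to the auto-thresholds.

    ``counts[k]`` is the number of pixels at gray level ``k``;
    ``total`` equals the pixel count of the source image.
    """

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (GRAY_LEVELS,):
            raise DimensionError(f"histogram must have {GRAY_LEVELS} bins, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Bin probabilities P_k = counts[k] / total."""
        return self.counts / self.total


def compute_histogram(image: np.ndarray) -> IntensityHistogram:
    """Tally the 256-bin histogram of an 8-bit gray image."""
    arr = as_gray8(image)
    return IntensityHistogram(np.bincount(arr.ravel(), minlength=GRAY_LEVELS))
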