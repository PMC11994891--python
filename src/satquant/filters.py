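"""Grayscale preprocessing operators shared by the three channel chains.

All filters consume and produce 8-bit gray images, handle borders by edge
replication, and are fully deterministic.  The rolling-ball background is
the exact spherical-cap grayscale opening (erosion then dilation by the
cap height profile), not the historical shrink/enlarge approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import DimensionError, ParameterError
from .imaging import as_gray8, round_half_up

__all__ = [
    "NormalizationParams",
    "RollingBallParams",
    "ball_cap",
    "rolling_ball_subtract",
    "sharpen",
    "edge_magnitude",
    "normalize_range",
    "median_filter",
    "convolve_kernel",
]

#: Classic sharpening kernel: 3x3 with center 12, -1 elsewhere, gain 1/4.
SHARPEN_KERNEL = np.array(
    [[-1.0, -1.0, -1.0],
     [-1.0, 12.0, -1.0],
     [-1.0, -1.0, -1.0]]
) / 4.0


@dataclass(frozen=True)
class NormalizationParams:
    """Min–max luminance stretch parameters.

    ``a``/``b`` are the source minimum/maximum (``None`` means take them
    from the image); ``(c, d)`` is the target range, default (0, 255).
    """

    a: float | None = None
    b: float | None = None
    c: float = 0.0
    d: float = 255.0

    def __post_init__(self):
        if self.c >= self.d:
            raise ParameterError(f"target range requires c < d, got ({self.c}, {self.d})")
        if self.a is not None and self.b is not None and self.a > self.b:
            raise ParameterError(f"source range requires a <= b, got ({self.a}, {self.b})")


@dataclass(frozen=True)
class RollingBallParams:
    """Ball radius (pixels) for rolling-ball background estimation."""

    radius: int = 25

    def __post_init__(self):
        if self.radius < 1:
            raise ParameterError(f"ball radius must be >= 1, got {self.radius}")


def ball_cap(radius: int) -> np.ndarray:
    """Height profile of the upper spherical cap of a ball of given radius.

    Entries outside the circular footprint are ``-inf`` so they never
    participate in the grayscale erosion/dilation.
    """
    d = np.arange(-radius, radius + 1)
    yy, xx = np.meshgrid(d, d, indexing="ij")
    rr2 = yy * yy + xx * xx
    inside = rr2 <= radius * radius
    cap = np.full(inside.shape, -np.inf, dtype=np.float32)
    cap[inside] = np.sqrt(radius * radius - rr2[inside])
    return cap


def rolling_ball_subtract(image: np.ndarray, params: RollingBallParams | int = RollingBallParams()) -> np.ndarray:
    """Subtract the rolling-ball background estimate from *image*.

    The background is the grayscale opening of the image by the spherical
    cap of the given radius: rolling a ball of that radius beneath the
    intensity surface and taking the surface the ball's top sweeps out.
    Output is ``clamp(image - background, 0, 255)``; no pixel ever
    increases.  Flat backgrounds (including constant images) are removed
    completely.
    """
    arr = as_gray8(image)
    if isinstance(params, (int, np.integer)):
        params = RollingBallParams(int(params))
    r = params.radius
    if r > arr.shape[0] and r > arr.shape[1]:
        raise ParameterError(
            f"ball radius {r} exceeds both image dimensions {arr.shape}"
        )
    cap = ball_cap(r)
    f = arr.astype(np.float32)
    eroded = ndi.grey_erosion(f, structure=cap, mode="nearest")
    background = ndi.grey_dilation(eroded, structure=cap, mode="nearest")
    np.maximum(background, 0.0, out=background)
    out = round_half_up(np.clip(f - background, 0.0, 255.0))
    return out.astype(np.uint8)


def _convolve_float(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True spatial convolution with edge replication, in float64."""
    return ndi.convolve(image.astype(np.float64), np.asarray(kernel, dtype=np.float64), mode="nearest")


def convolve_kernel(image: np.ndarray, kernel, normalize: bool = False) -> np.ndarray:
    """Convolve an image with an odd-sized kernel, clamped back to [0, 255].

    With ``normalize=True`` the result is divided by the kernel sum
    (skipped when the sum is zero, e.g. for derivative kernels).
    """
    arr = as_gray8(image)
    k = np.asarray(kernel, dtype=np.float64)
    if k.ndim != 2 or k.shape[0] % 2 == 0 or k.shape[1] % 2 == 0:
        raise ParameterError(f"kernel must be 2-D with odd dimensions, got shape {k.shape}")
    out = _convolve_float(arr, k)
    if normalize:
        s = k.sum()
        if s != 0:
            out = out / s
    return round_half_up(np.clip(out, 0.0, 255.0)).astype(np.uint8)


def sharpen(image: np.ndarray) -> np.ndarray:
    """Sharpness filter: 3x3 kernel (center 12, -1 elsewhere) / 4.

    The coefficients sum to one, so constant regions are unchanged while
    local contrast around signal is boosted.
    """
    arr = as_gray8(image)
    out = _convolve_float(arr, SHARPEN_KERNEL)
    return round_half_up(np.clip(out, 0.0, 255.0)).astype(np.uint8)


def edge_magnitude(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude sqrt(Gx^2 + Gy^2), clamped to [0, 255].

    Emphasizes signal outlines: interiors of constant regions map to 0 and
    step edges saturate.
    """
    arr = as_gray8(image).astype(np.float64)
    gx = ndi.sobel(arr, axis=1, mode="nearest")
    gy = ndi.sobel(arr, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    return round_half_up(np.clip(mag, 0.0, 255.0)).astype(np.uint8)


def normalize_range(image: np.ndarray, params: NormalizationParams = NormalizationParams()) -> np.ndarray:
    """Linear luminance stretch Py = (Px - a)(d - c)/(b - a) + c, rounded.

    ``a``/``b`` default to the image minimum/maximum.  A constant image is
    a degenerate stretch: the result is constant ``c`` and a warning is
    emitted.
    """
    arr = as_gray8(image)
    a = float(arr.min()) if params.a is None else float(params.a)
    b = float(arr.max()) if params.b is None else float(params.b)
    if a == b:
        warnings.warn(
            "normalize_range: constant image (a == b); returning constant c",
            stacklevel=2,
        )
        return np.full(arr.shape, int(round(params.c)), dtype=np.uint8)
    stretched = (arr.astype(np.float64) - a) * (params.d - params.c) / (b - a) + params.c
    return round_half_up(np.clip(stretched, 0.0, 255.0)).astype(np.uint8)


def median_filter(image: np.ndarray, radius: int = 1) -> np.ndarray:
    """Replace each pixel by the median of its (2r+1)x(2r+1) neighborhood."""
    arr = as_gray8(image)
    if radius < 1:
        raise ParameterError(f"median radius must be >= 1, got {radius}")
    return ndi.median_filter(arr, size=2 * radius + 1, mode="nearest")
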