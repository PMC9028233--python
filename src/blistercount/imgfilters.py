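"""Low-level image primitives shared by all pipeline stages.

Conventions: grayscale images ("GrayImage") are 2-D float arrays with
intensities in [0, 1], indexed (row, col) with the origin at the top
left.  Binary images ("BinaryImage") are 2-D boolean arrays, ``True``
meaning foreground/white.  All filters preserve image dimensions.

Neighbourhood filters use reflect padding at the borders.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, feature, filters

from .errors import InvalidParameterError

__all__ = [
    "median_smooth",
    "local_std",
    "otsu_threshold",
    "morph_consolidate",
    "clahe_equalize",
    "unsharp_sharpen",
    "canny_edges",
]


def _check_gray(img: np.ndarray, name: str = "img") -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise InvalidParameterError(f"{name} must be a non-empty 2-D array")
    return img


def _check_odd(size: int) -> int:
    size = int(size)
    if size < 3 or size % 2 == 0:
        raise InvalidParameterError(f"neighbourhood size must be odd and >= 3, got {size}")
    return size


def median_smooth(img: np.ndarray, size: int = 5) -> np.ndarray:
    """Median filter with a ``size`` x ``size`` neighbourhood.

    Suppresses sensor noise while preserving edges; the first step of
    blister localisation.
    """
    img = _check_gray(img)
    size = _check_odd(size)
    return ndi.median_filter(img, size=size, mode="reflect")


def local_std(img: np.ndarray, size: int = 9) -> np.ndarray:
    """Sample standard deviation over a ``size`` x ``size`` neighbourhood.

    Highlights contours and heterogeneous texture; a flat region maps to
    zero.  Uses the unbiased (n-1) normalisation.
    """
    img = _check_gray(img)
    size = _check_odd(size)
    n = size * size
    mean = ndi.uniform_filter(img, size=size, mode="reflect")
    meansq = ndi.uniform_filter(img * img, size=size, mode="reflect")
    # variance via E[x^2] - E[x]^2, rescaled to the sample estimator
    var = (meansq - mean * mean) * (n / (n - 1))
    np.clip(var, 0.0, None, out=var)
    return np.sqrt(var)


def otsu_threshold(img: np.ndarray) -> tuple[float, np.ndarray]:
    """Global threshold by Otsu's method over a 256-bin histogram.

    Returns ``(threshold, binary)`` where ``binary = img > threshold``.
    A constant image yields the constant itself as threshold and an
    all-background binary (there is no heterogeneous area to separate).
    """
    img = _check_gray(img)
    lo, hi = float(img.min()), float(img.max())
    if lo == hi:
        return lo, np.zeros(img.shape, dtype=bool)
    t = float(filters.threshold_otsu(img, nbins=256))
    return t, img > t


def _dilate(binary: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    # morphological dilation by a flat rectangle == running maximum filter
    return ndi.maximum_filter(binary, size=shape, mode="constant", cval=0)


def _erode(binary: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return ndi.minimum_filter(binary, size=shape, mode="constant", cval=1)


def morph_consolidate(binary: np.ndarray, line: int = 50, square: int = 50) -> np.ndarray:
    """Merge nearby foreground structure into consolidated blobs.

    Two consecutive dilations with a horizontal and a vertical line of
    ``line`` pixels, followed by a closing with a ``square`` x ``square``
    square.  Connects the separate contours of a blister into one
    component while leaving genuinely isolated specks small.
    """
    binary = np.asarray(binary).astype(bool)
    if binary.ndim != 2 or binary.size == 0:
        raise InvalidParameterError("binary must be a non-empty 2-D array")
    out = _dilate(binary, (1, line))
    out = _dilate(out, (line, 1))
    # closing with a square; rectangle ops are separable into line ops
    out = _dilate(out, (square, 1))
    out = _dilate(out, (1, square))
    out = _erode(out, (square, 1))
    out = _erode(out, (1, square))
    return out


def clahe_equalize(channel: np.ndarray, tiles: int = 8, clip: float = 0.005) -> np.ndarray:
    """Contrast limited adaptive histogram equalisation.

    ``tiles`` x ``tiles`` contextual regions, clip limit ``clip`` on the
    [0, 1] scale.  A constant channel is returned unchanged.
    """
    channel = _check_gray(channel, "channel")
    if channel.min() == channel.max():
        return channel.copy()
    h, w = channel.shape
    kernel = (max(1, int(np.ceil(h / tiles))), max(1, int(np.ceil(w / tiles))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # precision warnings on float input
        out = exposure.equalize_adapthist(
            np.clip(channel, 0.0, 1.0), kernel_size=kernel, clip_limit=clip, nbins=256
        )
    return np.clip(out, 0.0, 1.0)


def unsharp_sharpen(channel: np.ndarray, radius: float = 6.0, strength: float = 60.0) -> np.ndarray:
    """Unsharp masking: amplify the difference to a Gaussian-blurred copy.

    ``strength`` is a percentage; the applied amount is ``strength / 100``
    so the published "radius 6, strength 60" maps to
    ``out = clip(x + 0.6 * (x - gaussian(x, 6)), 0, 1)``.
    """
    channel = _check_gray(channel, "channel")
    if radius <= 0:
        raise InvalidParameterError(f"radius must be positive, got {radius}")
    amount = strength / 100.0
    blurred = ndi.gaussian_filter(channel, sigma=radius, mode="reflect")
    return np.clip(channel + amount * (channel - blurred), 0.0, 1.0)


def canny_edges(
    channel: np.ndarray,
    sigma: float = 2.0,
    low_ratio: float = 0.4,
    high_floor: float = 0.1,
) -> np.ndarray:
    """Canny edge detection with per-image automatic thresholds.

    The high hysteresis threshold is chosen by Otsu's method on the
    Sobel gradient magnitude of the Gaussian-smoothed channel, the low
    threshold is ``low_ratio`` times the high one, so the detector reacts
    dynamically to the contrast of each image.  ``high_floor`` bounds the
    high threshold from below: gradients at the sensor-noise scale are
    never edges, so a structureless image yields no edge pixels instead
    of a noise split.  Returns a binary image of one-pixel-thick edges.
    """
    channel = _check_gray(channel, "channel")
    smoothed = ndi.gaussian_filter(channel, sigma=sigma, mode="reflect")
    # same gradient the hysteresis stage thresholds (unnormalised Sobel)
    grad = np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1))
    if grad.max() <= 0:
        return np.zeros(channel.shape, dtype=bool)
    high, _ = otsu_threshold(grad)
    high = max(high, high_floor)
    low = low_ratio * high
    return feature.canny(
        channel, sigma=sigma, low_threshold=low, high_threshold=high
    )
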