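"""Automatic blister localisation in a raw photograph.

The blister is found as the largest consolidated region of image
heterogeneity: grayscale -> median smoothing -> local-standard-deviation
texture filter -> Otsu binarisation -> consolidating morphology ->
largest 8-connected component -> bounding box.  Works best on flat,
plain backgrounds; cluttered scenes (hands, desks) defeat it, in which
case callers fall back to a manual crop.

The fixed 50-px structuring elements presuppose a bounded image size, so
detection runs at a working resolution (long edge capped, default
1500 px) and the box is mapped back to native coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.color import rgb2gray
from skimage.transform import resize

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import BlisterNotFoundError, InvalidParameterError
from .imgfilters import local_std, median_smooth, morph_consolidate, otsu_threshold

__all__ = ["BoundingBox", "detect_blister", "crop"]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open: rows [top, top+height)."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise InvalidParameterError("bounding box must have positive size")
        if self.top < 0 or self.left < 0:
            raise InvalidParameterError("bounding box must have non-negative origin")

    @property
    def bottom(self) -> int:
        return self.top + self.height

    @property
    def right(self) -> int:
        return self.left + self.width

    def within(self, shape: tuple[int, ...]) -> bool:
        return self.bottom <= shape[0] and self.right <= shape[1]


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        return rgb2gray(img)
    return img


def detect_blister(img: np.ndarray, config: PipelineConfig = DEFAULT_CONFIG) -> BoundingBox:
    """Locate the blister in ``img`` and return its bounding box.

    Parameters
    ----------
    img : ndarray
        RGB (H, W, 3) or grayscale (H, W) photograph, intensities in [0, 1].

    Returns
    -------
    BoundingBox
        The smallest enclosing rectangle of the largest heterogeneous
        component, in native image coordinates.

    Raises
    ------
    BlisterNotFoundError
        If no foreground component survives thresholding and morphology
        (e.g. a structureless image).
    """
    gray = _to_gray(img)
    if gray.size == 0:
        raise InvalidParameterError("empty image")
    h, w = gray.shape
    long_edge = max(h, w)
    scale = 1.0
    if long_edge > config.detect_long_edge:
        scale = config.detect_long_edge / long_edge
        gray = resize(
            gray,
            (max(1, round(h * scale)), max(1, round(w * scale))),
            order=1,
            anti_aliasing=True,
            preserve_range=True,
        )

    smoothed = median_smooth(gray, config.median_size)
    texture = local_std(smoothed, config.std_size)
    _, binary = otsu_threshold(texture)
    if not binary.any():
        raise BlisterNotFoundError("no heterogeneous area found")
    consolidated = morph_consolidate(binary, config.morph_line, config.morph_square)
    if not consolidated.any():
        raise BlisterNotFoundError("no foreground after morphology")

    labels = measure.label(consolidated, connectivity=2)
    props = measure.regionprops(labels)
    # largest component; ties by larger box area, then topmost-leftmost
    props.sort(
        key=lambda p: (
            -p.area,
            -(p.bbox[2] - p.bbox[0]) * (p.bbox[3] - p.bbox[1]),
            p.bbox[0],
            p.bbox[1],
        )
    )
    r0, c0, r1, c1 = props[0].bbox

    if scale != 1.0:
        r0 = int(np.floor(r0 / scale))
        c0 = int(np.floor(c0 / scale))
        r1 = int(np.ceil(r1 / scale))
        c1 = int(np.ceil(c1 / scale))
    r0, c0 = max(0, r0), max(0, c0)
    r1, c1 = min(h, r1), min(w, c1)
    return BoundingBox(top=r0, left=c0, height=r1 - r0, width=c1 - c0)


def crop(img: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Extract the pixels of ``box`` from ``img`` (values copied unchanged)."""
    img = np.asarray(img)
    if img.ndim not in (2, 3):
        raise InvalidParameterError("image must be 2-D or 3-D")
    if not box.within(img.shape):
        raise InvalidParameterError(
            f"box {box} exceeds image bounds {img.shape[:2]}"
        )
    return img[box.top : box.bottom, box.left : box.right].copy()
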