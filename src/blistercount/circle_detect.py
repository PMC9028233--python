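"""Circle detection and per-circle features.

Pills and pill pockets appear as circular rims in the Canny edge image
of the preprocessed value channel.  They are detected with the Circle
Hough Transform (CHT): every edge pixel votes for all circle centers at
each candidate radius, and circles are local maxima of the accumulator.
Each detection carries a "metric" in [0, 1] — the accumulator peak
normalised by the ideal perimeter pixel count of its radius, so 1 means
a fully supported circular edge.

Two features measured inside a detected circle's disk feed artifact
rejection and present/taken classification:

* the *circle edge ratio* (CER) — the fraction of edge pixels among all
  pixels of the disk; rises when a pocket rim is deformed;
* the *mean local standard deviation* — disk mean of the 9x9 local-std
  filtered value channel; rises with the surface heterogeneity of an
  emptied, crumpled pocket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from skimage.draw import circle_perimeter

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import InvalidParameterError
from .imgfilters import local_std

__all__ = [
    "DetectedCircle",
    "CircleFeatures",
    "hough_circles",
    "circle_edge_ratio",
    "local_std_mean",
    "compute_features",
]


@dataclass(frozen=True)
class DetectedCircle:
    """A circle found by the Hough stage (0-based pixel coordinates)."""

    center_row: float
    center_col: float
    radius: float
    metric: float


@dataclass(frozen=True)
class CircleFeatures:
    """Disk features used for artifact rejection and pocket classification."""

    circle_edge_ratio: float
    local_std_mean: float


# The ring-kernel spectra depend only on the padded transform shape and
# the radius grid, so consecutive same-shaped images (e.g. the frames of
# one blister sequence) share them.  A full radius band of spectra is a
# few hundred MB, so only the most recent shape is kept.
_KERNEL_CACHE: list = [None, None]  # [key, kernels]


def _ring_kernel_ffts(
    shape: tuple[int, int], radii: np.ndarray
) -> list[tuple[np.ndarray, float]]:
    key = (shape, int(radii[0]), int(radii[-1]), len(radii))
    if _KERNEL_CACHE[0] != key:
        kernels = []
        for r in radii:
            r = int(r)
            k = np.zeros((2 * r + 1, 2 * r + 1), dtype=np.float32)
            rr, cc = circle_perimeter(r, r, r)
            k[rr, cc] = 1.0
            kernels.append((sfft.rfft2(k, shape), float(k.sum())))
        _KERNEL_CACHE[0] = key
        _KERNEL_CACHE[1] = kernels
    return _KERNEL_CACHE[1]


def hough_accumulator(edges: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Circle Hough Transform accumulator, normalised per radius.

    Every edge pixel casts a full ring of votes for each candidate
    radius (no gradient information is used); plane ``i`` holds the vote
    counts for ``radii[i]`` divided by that radius's ideal perimeter
    pixel count, so a fully supported circle scores 1.  The ring
    convolutions are evaluated via FFT.
    """
    h, w = edges.shape
    rmax = int(radii[-1])
    padded = (sfft.next_fast_len(h + 2 * rmax), sfft.next_fast_len(w + 2 * rmax))
    kernels = _ring_kernel_ffts(padded, radii)
    spectrum = sfft.rfft2(edges.astype(np.float32), padded)
    accum = np.empty((len(radii), h, w), dtype=np.float32)
    for i, r in enumerate(radii):
        r = int(r)
        kernel_fft, support = kernels[i]
        full = sfft.irfft2(spectrum * kernel_fft, padded)
        accum[i] = full[r : r + h, r : r + w] / support
    # FFT round-off can leave tiny negatives on empty regions
    np.clip(accum, 0.0, None, out=accum)
    return accum


def hough_circles(
    edges: np.ndarray,
    rmin: int = 30,
    rmax: int = 130,
    sensitivity: float = 0.6,
    radius_step: int = 1,
) -> list[DetectedCircle]:
    """Detect circles with radii in [rmin, rmax] in a binary edge image.

    Accumulator peaks whose normalised support (metric) exceeds
    ``1 - sensitivity`` are returned, non-maximum suppressed so that no
    two centers lie within ``rmin`` of each other (per axis), sorted by
    metric descending with deterministic position tie-breaking.

    An empty edge image yields an empty list.
    """
    if not (0 < sensitivity < 1):
        raise InvalidParameterError(f"sensitivity must be in (0, 1), got {sensitivity}")
    if rmin >= rmax or rmin <= 0:
        raise InvalidParameterError(f"need 0 < rmin < rmax, got {rmin}, {rmax}")
    edges = np.asarray(edges).astype(bool)
    if edges.ndim != 2:
        raise InvalidParameterError("edge image must be 2-D")
    if not edges.any():
        return []

    radii = np.arange(rmin, rmax + 1, radius_step)
    accum = hough_accumulator(edges, radii)
    threshold = 1.0 - sensitivity

    # sparse peak extraction: candidates above threshold, strongest first,
    # suppressing any weaker candidate whose center lies within rmin
    # (per axis) of an already selected one, at any radius
    ri, rows, cols = np.nonzero(accum > threshold)
    if len(ri) == 0:
        return []
    values = accum[ri, rows, cols]
    order = np.lexsort((radii[ri], cols, rows, -values))
    selected: list[tuple[float, int, int, int]] = []
    for idx in order:
        r, c = int(rows[idx]), int(cols[idx])
        if any(abs(r - sr) < rmin and abs(c - sc) < rmin for _, sr, sc, _ in selected):
            continue
        selected.append((float(values[idx]), r, c, int(radii[ri[idx]])))

    circles = [
        DetectedCircle(
            center_row=float(r),
            center_col=float(c),
            radius=float(rad),
            metric=float(min(m, 1.0)),
        )
        for m, r, c, rad in selected
    ]
    circles.sort(key=lambda d: (-d.metric, d.center_row, d.center_col, d.radius))
    return circles


def _disk_mask(
    circle: DetectedCircle, shape: tuple[int, int]
) -> tuple[slice, slice, np.ndarray]:
    """Boolean mask of the closed disk, clipped to the image bounds."""
    h, w = shape
    r0 = max(0, int(np.floor(circle.center_row - circle.radius)))
    r1 = min(h, int(np.ceil(circle.center_row + circle.radius)) + 1)
    c0 = max(0, int(np.floor(circle.center_col - circle.radius)))
    c1 = min(w, int(np.ceil(circle.center_col + circle.radius)) + 1)
    if r0 >= r1 or c0 >= c1:
        raise InvalidParameterError("circle lies entirely outside the image")
    rr, cc = np.ogrid[r0:r1, c0:c1]
    # half-pixel dilation: pixels the circle itself passes through count
    # as inside, so rim edge pixels belong to their pill's disk
    reach = (circle.radius + 0.5) ** 2
    mask = (rr - circle.center_row) ** 2 + (cc - circle.center_col) ** 2 <= reach
    return slice(r0, r1), slice(c0, c1), mask


def circle_edge_ratio(circle: DetectedCircle, edges: np.ndarray) -> float:
    """Fraction of edge (white) pixels among all pixels in the circle's disk.

    A circle partially outside the image is clipped; only in-bounds disk
    pixels are counted.
    """
    edges = np.asarray(edges).astype(bool)
    rs, cs, mask = _disk_mask(circle, edges.shape)
    total = int(mask.sum())
    if total == 0:
        return 0.0
    return float(edges[rs, cs][mask].sum() / total)


def local_std_mean(
    circle: DetectedCircle, value: np.ndarray, std_size: int = 9, std_map: np.ndarray | None = None
) -> float:
    """Mean of the local-standard-deviation image over the circle's disk.

    ``std_map`` may carry a precomputed ``local_std(value, std_size)`` to
    avoid refiltering when many circles are measured on one image.
    """
    if std_map is None:
        std_map = local_std(np.asarray(value, dtype=np.float64), std_size)
    rs, cs, mask = _disk_mask(circle, std_map.shape)
    sel = std_map[rs, cs][mask]
    if sel.size == 0:
        return 0.0
    return float(sel.mean())


def compute_features(
    circles: list[DetectedCircle],
    edges: np.ndarray,
    value: np.ndarray,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[CircleFeatures]:
    """CER and mean local std for each circle, sharing one local-std pass."""
    std_map = local_std(np.asarray(value, dtype=np.float64), config.std_size)
    return [
        CircleFeatures(
            circle_edge_ratio=circle_edge_ratio(c, edges),
            local_std_mean=local_std_mean(c, value, config.std_size, std_map=std_map),
        )
        for c in circles
    ]
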