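"""Counting mode: label each reference pill pocket present or taken.

A (possibly partially used) blister image of a registered blister form
is analysed with the same edge + Circle Hough machinery as registration.
Emptied pockets are themselves often detected as circles, so mean-based
artifact rules are useless here; instead every detected circle is
matched to the nearest reference pill position and its disk features are
compared against the stored reference means:

* a local-standard-deviation increase above 0.05 marks the pocket taken
  outright (the crumpled empty pocket is much more heterogeneous);
* an intermediate increase (0.02, 0.05] makes the decision depend on the
  circle-edge ratio: an increase of at least 0.025 also marks it taken;
* otherwise the pocket holds a pill (present).

Reference positions with no circle within ``mean_radius + 10`` px are
taken by definition.  For blisters with an odd pill count (asymmetric
layouts), counting is tried on the image and on its 180-degree rotation
and the orientation whose detected circles lie closer to the reference
positions wins, so an upside-down photograph cannot scramble the
pocket-to-reference assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circle_detect import (
    DetectedCircle,
    circle_edge_ratio,
    local_std_mean,
    hough_circles,
)
from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import IncompatibleReferenceError
from .imgfilters import canny_edges, local_std
from .preprocess import PreprocessedImage
from .registration import BlisterReference

__all__ = [
    "PocketAssessment",
    "CountResult",
    "match_circles",
    "classify_pocket",
    "disambiguate_orientation",
    "count",
]


@dataclass(frozen=True)
class PocketAssessment:
    """Outcome for one reference pill position."""

    reference_index: int
    matched_circle: DetectedCircle | None
    delta_local_std: float | None
    delta_cer: float | None
    label: str  # "present" | "taken"


@dataclass(frozen=True)
class CountResult:
    """Aggregate counting-mode outcome for one image."""

    assessments: tuple[PocketAssessment, ...]
    n_present: int
    n_taken: int
    orientation_used: str  # "original" | "rotated180"

    def __post_init__(self) -> None:
        assert self.n_present == sum(a.label == "present" for a in self.assessments)
        assert self.n_present + self.n_taken == len(self.assessments)


def match_circles(
    ref: BlisterReference,
    circles: list[DetectedCircle],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[DetectedCircle | None]:
    """Assign detected circles to reference pill positions.

    For each reference center, candidate circles lie within Euclidean
    distance ``mean_radius + match_slack``; among a position's candidates
    the one with the smallest radius deviation from the reference mean
    radius is preferred.  Assignment is greedy in increasing
    candidate distance and one-to-one: each circle serves at most one
    position.  Unmatched positions map to ``None``.
    """
    n_ref = len(ref.pill_centers)
    matches: list[DetectedCircle | None] = [None] * n_ref
    if not circles:
        return matches
    limit = ref.mean_radius + config.match_slack
    centers = np.array(ref.pill_centers)
    pos = np.array([[c.center_row, c.center_col] for c in circles])
    dist = np.linalg.norm(centers[:, None, :] - pos[None, :, :], axis=2)
    rdev = np.abs(np.array([c.radius for c in circles]) - ref.mean_radius)

    unmatched = set(range(n_ref))
    free = set(range(len(circles)))
    while unmatched and free:
        # reference position with the closest free candidate goes first
        best = None
        for i in unmatched:
            for j in free:
                if dist[i, j] <= limit:
                    key = (dist[i, j], i, j)
                    if best is None or key < best[0]:
                        best = (key, i)
        if best is None:
            break
        _, i = best
        # among this position's candidates, smallest radius deviation wins
        cands = [j for j in free if dist[i, j] <= limit]
        j = min(cands, key=lambda j: (rdev[j], dist[i, j], j))
        matches[i] = circles[j]
        unmatched.discard(i)
        free.discard(j)
    return matches


def classify_pocket(
    delta_std: float,
    delta_cer: float,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> str:
    """Label one pocket from its feature increases over the reference means.

    ``taken`` iff the local-std increase exceeds ``taken_std_delta``, or
    it lies in (``consult_std_delta``, ``taken_std_delta``] and the CER
    increase is at least ``taken_cer_delta``; otherwise ``present``.
    """
    if delta_std > config.taken_std_delta:
        return "taken"
    if delta_std > config.consult_std_delta and delta_cer >= config.taken_cer_delta:
        return "taken"
    return "present"


def _rotate_circles_180(
    circles: list[DetectedCircle], shape: tuple[int, int]
) -> list[DetectedCircle]:
    h, w = shape
    return [
        DetectedCircle(
            center_row=(h - 1) - c.center_row,
            center_col=(w - 1) - c.center_col,
            radius=c.radius,
            metric=c.metric,
        )
        for c in circles
    ]


def _nearest_distance_total(
    ref: BlisterReference, circles: list[DetectedCircle]
) -> float:
    """Sum over reference pills of the distance to the closest circle."""
    if not circles:
        return float("inf")
    centers = np.array(ref.pill_centers)
    pos = np.array([[c.center_row, c.center_col] for c in circles])
    dist = np.linalg.norm(centers[:, None, :] - pos[None, :, :], axis=2)
    return float(dist.min(axis=1).sum())


def disambiguate_orientation(
    pre: PreprocessedImage,
    ref: BlisterReference,
    circles: list[DetectedCircle] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> str:
    """Decide whether the image should be counted as-is or rotated 180 deg.

    Even pill counts are 180-degree ambiguous anyway, so the original
    orientation is used without further checks.  For odd counts the
    closest-circle distances to the reference positions are summed for
    both orientations and the smaller total wins; ties go to the
    original.

    A 180-degree rotation maps the Hough accumulator onto itself, so the
    rotated orientation is evaluated by transforming the detected circle
    coordinates rather than re-detecting.
    """
    if ref.pill_count % 2 == 0:
        return "original"
    if circles is None:
        edges = canny_edges(
            pre.value, config.canny_sigma, config.canny_low_ratio, config.canny_high_floor
        )
        circles = hough_circles(
            edges,
            config.hough_rmin,
            config.hough_rmax,
            config.hough_sensitivity,
            config.hough_radius_step,
        )
    d_orig = _nearest_distance_total(ref, circles)
    d_rot = _nearest_distance_total(ref, _rotate_circles_180(circles, pre.shape))
    return "rotated180" if d_rot < d_orig else "original"


def count(
    pre: PreprocessedImage,
    ref: BlisterReference,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> CountResult:
    """Count present vs taken pills in a preprocessed blister image.

    Raises
    ------
    IncompatibleReferenceError
        If the image's long edge differs from the reference's by more
        than ``config.ref_long_edge_tol`` (the coordinate comparison
        presumes similar crops).
    """
    h, w = pre.shape
    ref_long = max(ref.image_height, ref.image_width)
    if abs(max(h, w) - ref_long) / ref_long > config.ref_long_edge_tol:
        raise IncompatibleReferenceError(
            f"image long edge {max(h, w)} vs reference {ref_long}"
        )

    edges = canny_edges(
        pre.value, config.canny_sigma, config.canny_low_ratio, config.canny_high_floor
    )
    circles = hough_circles(
        edges,
        config.hough_rmin,
        config.hough_rmax,
        config.hough_sensitivity,
        config.hough_radius_step,
    )
    orientation = disambiguate_orientation(pre, ref, circles, config)
    value = pre.value
    if orientation == "rotated180":
        circles = _rotate_circles_180(circles, pre.shape)
        value = np.rot90(value, k=2)
        edges = np.rot90(edges, k=2)

    matches = match_circles(ref, circles, config)
    std_map = local_std(value, config.std_size)

    assessments = []
    for i, circle in enumerate(matches):
        if circle is None:
            assessments.append(
                PocketAssessment(
                    reference_index=i,
                    matched_circle=None,
                    delta_local_std=None,
                    delta_cer=None,
                    label="taken",
                )
            )
            continue
        d_std = local_std_mean(circle, value, config.std_size, std_map=std_map) - ref.mean_local_std
        d_cer = circle_edge_ratio(circle, edges) - ref.mean_circle_edge_ratio
        assessments.append(
            PocketAssessment(
                reference_index=i,
                matched_circle=circle,
                delta_local_std=d_std,
                delta_cer=d_cer,
                label=classify_pocket(d_std, d_cer, config),
            )
        )
    n_present = sum(a.label == "present" for a in assessments)
    return CountResult(
        assessments=tuple(assessments),
        n_present=n_present,
        n_taken=len(assessments) - n_present,
        orientation_used=orientation,
    )
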