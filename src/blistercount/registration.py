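"""Registration mode: extract per-blister reference values from a full blister.

A full blister is assumed, so most detected circles are genuine pills and
population (mean-based) statistics are trustworthy.  Artifacts from
rounded blister corners, embossing and residual reflections are discarded
by a cascade of rules:

1. *radius rule* — circles whose radius deviates more than 50% from the
   mean radius are artifacts;
2. *circle-edge-ratio rule* — when the CER spread across circles is
   informative (std >= 0.04), circles outside mean +/- 2 std are
   discarded; a small spread means the image is already clean and the
   rule is skipped;
3. *metric rescue* — when the mean circularity metric is informative
   (> 0.15), any CER-discarded circle whose metric exceeds 75% of the
   metric median is re-accepted (prevents rejecting pills that merely
   carry a reflection or slight deformation);
4. *x-position rule* — pills sit in vertical columns after alignment;
   in the outermost left/right columns, circles deviating from their
   column's median position by more than 5% of the image width must
   additionally satisfy stricter CER and metric limits.

The surviving circles are the pills; their centers and the means of
radius, CER and local standard deviation form the blister's reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circle_detect import (
    CircleFeatures,
    DetectedCircle,
    compute_features,
    hough_circles,
)
from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import InvalidParameterError, RegistrationFailedError
from .imgfilters import canny_edges
from .preprocess import PreprocessedImage

__all__ = ["BlisterReference", "reject_artifacts", "register"]


@dataclass(frozen=True)
class BlisterReference:
    """Reference record of a registered blister.

    Pill centers are in normalised (1000-px long edge, vertical)
    coordinates; the four statistics are the means over all accepted
    pills.
    """

    blister_id: str
    pill_centers: tuple[tuple[float, float], ...]
    mean_radius: float
    mean_circle_edge_ratio: float
    mean_local_std: float
    pill_count: int
    image_height: int
    image_width: int
    config_digest: str = ""
    created_at: str = ""

    def __post_init__(self) -> None:
        if self.pill_count != len(self.pill_centers) or self.pill_count < 1:
            raise InvalidParameterError("pill_count must equal number of centers (>= 1)")
        for r, c in self.pill_centers:
            if not (0 <= r < self.image_height and 0 <= c < self.image_width):
                raise InvalidParameterError("pill center outside image bounds")


def reject_artifacts(
    circles: list[DetectedCircle],
    features: list[CircleFeatures],
    image_width: int,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[int]:
    """Apply the registration artifact-rejection cascade.

    Returns the indices (into ``circles``) of the accepted pills, in
    input order.  The decision for each circle depends only on the
    population statistics, so the accepted set is invariant to input
    permutation.

    Raises
    ------
    RegistrationFailedError
        If every circle is rejected.
    """
    if len(circles) == 0:
        raise RegistrationFailedError("no circles to classify")
    if len(circles) != len(features):
        raise InvalidParameterError("circles and features must align")

    radius = np.array([c.radius for c in circles])
    metric = np.array([c.metric for c in circles])
    cer = np.array([f.circle_edge_ratio for f in features])
    col = np.array([c.center_col for c in circles])

    # (1) radius rule
    mean_r = radius.mean()
    keep = np.abs(radius - mean_r) / mean_r <= config.radius_rule_rel
    if not keep.any():
        raise RegistrationFailedError("all circles rejected by the radius rule")

    # statistics of the radius-rule survivors drive the remaining rules
    cer_mean = cer[keep].mean()
    cer_std = cer[keep].std(ddof=1) if keep.sum() > 1 else 0.0
    metric_mean = metric[keep].mean()
    metric_median = float(np.median(metric[keep]))

    # (2) circle-edge-ratio rule, only when the spread is informative
    cer_rejected = np.zeros_like(keep)
    if cer_std >= config.cer_std_threshold:
        lo = cer_mean - config.cer_band_sigmas * cer_std
        hi = cer_mean + config.cer_band_sigmas * cer_std
        cer_rejected = keep & ((cer < lo) | (cer > hi))
        keep = keep & ~cer_rejected

    # (3) metric rescue of CER-rejected circles
    if metric_mean > config.metric_mean_min and cer_rejected.any():
        rescued = cer_rejected & (metric > config.metric_rescue_frac * metric_median)
        keep = keep | rescued

    if not keep.any():
        raise RegistrationFailedError("all circles rejected by the edge-ratio rule")

    # (4) x-position rule on the outermost columns of each blister half.
    # The alignment anchor is the median column of the outermost-column
    # members themselves (for two-column blisters this coincides with the
    # half-blister median; for wider grids the half median falls between
    # columns and would flag every honest outer pill).
    mean_r_kept = radius[keep].mean()
    half = image_width / 2.0
    flagged = np.zeros_like(keep)
    for side in ("left", "right"):
        in_half = keep & ((col < half) if side == "left" else (col >= half))
        if not in_half.any():
            continue
        extreme = col[in_half].min() if side == "left" else col[in_half].max()
        outer = in_half & (np.abs(col - extreme) <= mean_r_kept)
        median_col = float(np.median(col[outer]))
        flagged |= outer & (np.abs(col - median_col) > config.x_rule_frac * image_width)
    if flagged.any():
        lo = cer_mean - config.x_rule_cer_sigmas * cer_std
        hi = cer_mean + config.x_rule_cer_sigmas * cer_std
        strict_ok = (cer >= lo) & (cer <= hi) & (metric >= metric_median)
        keep = keep & (~flagged | strict_ok)

    if not keep.any():
        raise RegistrationFailedError("all circles rejected by the x-position rule")
    return [i for i in range(len(circles)) if keep[i]]


def pill_mask(
    circles: list[DetectedCircle], shape: tuple[int, int]
) -> np.ndarray:
    """Binary union of the accepted pill disks."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for c in circles:
        mask |= (rr - c.center_row) ** 2 + (cc - c.center_col) ** 2 <= c.radius**2
    return mask


def register(
    pre: PreprocessedImage,
    blister_id: str,
    config: PipelineConfig = DEFAULT_CONFIG,
    drop_circles: tuple[int, ...] = (),
) -> tuple[BlisterReference, np.ndarray]:
    """Detect all pills in a preprocessed full blister and build its reference.

    Pipeline: Canny edges on the value channel -> Circle Hough Transform
    over the configured radius band -> disk features -> artifact
    rejection -> reference record plus the binary mask of accepted pills.

    ``drop_circles`` optionally removes accepted circles by index (the
    manual verification step for rare false positives).

    Raises
    ------
    RegistrationFailedError
        If no circles are detected or none survive artifact rejection.
    """
    from datetime import datetime, timezone

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
    if not circles:
        raise RegistrationFailedError(
            "no circular shapes detected; check the crop and image sharpness"
        )
    features = compute_features(circles, edges, pre.value, config)
    accepted_idx = reject_artifacts(circles, features, pre.shape[1], config)
    accepted_idx = [i for i in accepted_idx if i not in set(drop_circles)]
    if not accepted_idx:
        raise RegistrationFailedError("all accepted circles were dropped")

    acc = [circles[i] for i in accepted_idx]
    acc_feat = [features[i] for i in accepted_idx]
    ref = BlisterReference(
        blister_id=blister_id,
        pill_centers=tuple((c.center_row, c.center_col) for c in acc),
        mean_radius=float(np.mean([c.radius for c in acc])),
        mean_circle_edge_ratio=float(np.mean([f.circle_edge_ratio for f in acc_feat])),
        mean_local_std=float(np.mean([f.local_std_mean for f in acc_feat])),
        pill_count=len(acc),
        image_height=pre.shape[0],
        image_width=pre.shape[1],
        config_digest=config.digest(),
        created_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    return ref, pill_mask(acc, pre.shape)
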