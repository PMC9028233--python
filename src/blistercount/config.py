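"""Pipeline configuration.

Every tunable parameter of the pipeline lives in :class:`PipelineConfig`
so that the individual stages stay free of magic numbers and experiments
can override a single value without touching code.  The defaults encode
the published operating point of the method (filter neighbourhoods,
morphology element sizes, the Hough radius band and sensitivity, and the
artifact-rejection / pocket-classification thresholds).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the blister detection / registration / counting pipeline.

    Attributes
    ----------
    median_size : int
        Neighbourhood of the noise-reduction median filter (pixels, odd).
    std_size : int
        Neighbourhood of the local standard-deviation texture filter
        (pixels, odd).  Used both for blister localisation and for the
        per-pocket heterogeneity feature.
    morph_line : int
        Length of the horizontal/vertical line structuring elements of the
        two consolidation dilations (pixels).
    morph_square : int
        Side of the square structuring element of the closing that follows
        the dilations (pixels).
    detect_long_edge : int
        Working resolution of automatic blister detection: photographs are
        downscaled so the long edge does not exceed this many pixels before
        the fixed-size morphology runs; the resulting box is mapped back to
        native coordinates.
    norm_long_edge : int
        Long edge of the normalised (preprocessed) crop, pixels.
    min_crop_long_edge : int
        Crops smaller than this on the long edge are rejected as degenerate.
    clahe_tiles : int
        Contextual tile grid of CLAHE (``clahe_tiles`` x ``clahe_tiles``).
    clahe_clip : float
        CLAHE clip limit on the [0, 1] intensity scale.
    reflection_level : float
        Value-channel intensity above which a pixel is treated as a
        specular reflection and in-filled by inward interpolation.
    sharpen_radius : float
        Gaussian sigma of the unsharp mask, pixels.
    sharpen_strength : float
        Unsharp strength; interpreted as a percentage, i.e. the unsharp
        amount is ``sharpen_strength / 100``.
    canny_sigma : float
        Gaussian smoothing of the Canny edge detector.
    canny_low_ratio : float
        Low hysteresis threshold as a fraction of the high threshold; the
        high threshold itself is chosen per image by Otsu's method on the
        gradient-magnitude image.
    canny_high_floor : float
        Lower bound on the high threshold (on the unnormalised Sobel
        gradient scale); gradients at the sensor-noise scale never count
        as edges.
    hough_rmin, hough_rmax : int
        Radius band of the Circle Hough Transform (pixels, at the
        normalised resolution).  Circles outside the band are never
        reported.
    hough_radius_step : int
        Spacing of the radius grid searched by the accumulator.
    hough_sensitivity : float
        Detection sensitivity in (0, 1); accumulator peaks with normalised
        support (metric) above ``1 - hough_sensitivity`` are accepted.
    radius_rule_rel : float
        Registration artifact rule 1: discard circles whose radius deviates
        from the mean radius by more than this relative fraction.
    cer_std_threshold : float
        Registration rule 2: the circle-edge-ratio (CER) filter only runs
        when the CER standard deviation across circles reaches this value.
    cer_band_sigmas : float
        Width of the acceptable CER band, in standard deviations about the
        mean, when rule 2 runs.
    metric_mean_min : float
        Registration rule 3: the circularity metric is only considered
        informative when its mean exceeds this value.
    metric_rescue_frac : float
        Rule 3: a CER-rejected circle is re-accepted when its metric
        exceeds this fraction of the metric median.
    x_rule_frac : float
        Registration rule 4: in the outermost pill columns, circles whose
        x position deviates from the half-blister median column by more
        than this fraction of the image width are re-examined.
    x_rule_cer_sigmas : float
        Stricter CER band (in standard deviations) applied to flagged
        circles in rule 4.
    match_slack : float
        Counting mode: a detected circle is a candidate for a reference
        position when its center lies within ``mean_radius + match_slack``
        pixels of it.
    taken_std_delta : float
        Local-std increase over the reference mean that classifies a pocket
        as taken outright.
    consult_std_delta : float
        Local-std increase above which the circle-edge ratio is consulted.
    taken_cer_delta : float
        CER increase that, combined with an intermediate local-std
        increase, classifies a pocket as taken.
    ref_long_edge_tol : float
        Maximum relative long-edge mismatch between a counting image and
        its reference before the pair is declared incompatible.
    """

    # blister localisation
    median_size: int = 5
    std_size: int = 9
    morph_line: int = 50
    morph_square: int = 50
    detect_long_edge: int = 1500

    # preprocessing
    norm_long_edge: int = 1000
    min_crop_long_edge: int = 50
    clahe_tiles: int = 8
    clahe_clip: float = 0.005
    reflection_level: float = 0.95
    sharpen_radius: float = 6.0
    sharpen_strength: float = 60.0

    # edge and circle detection
    canny_sigma: float = 2.0
    canny_low_ratio: float = 0.4
    canny_high_floor: float = 0.1
    hough_rmin: int = 30
    hough_rmax: int = 130
    hough_radius_step: int = 1
    hough_sensitivity: float = 0.6

    # registration artifact rejection
    radius_rule_rel: float = 0.5
    cer_std_threshold: float = 0.04
    cer_band_sigmas: float = 2.0
    metric_mean_min: float = 0.15
    metric_rescue_frac: float = 0.75
    x_rule_frac: float = 0.05
    x_rule_cer_sigmas: float = 1.0

    # counting mode
    match_slack: float = 10.0
    taken_std_delta: float = 0.05
    consult_std_delta: float = 0.02
    taken_cer_delta: float = 0.025
    ref_long_edge_tol: float = 0.05

    def digest(self) -> str:
        """Short stable hash of the configuration, stored with references."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


DEFAULT_CONFIG = PipelineConfig()
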