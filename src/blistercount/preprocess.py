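"""Geometric and photometric normalisation of a cropped blister image.

A crop is scaled so its long edge is 1000 px, rotated to vertical
(height >= width), converted to HSV, and each channel is contrast
enhanced with CLAHE.  The value channel — the input to edge and circle
detection — additionally has specular reflections (> 0.95) removed by
inward interpolation and is sharpened by an unsharp mask, so that
pocket rims and deformations stand out for the later stages.

The ``(scale_factor, rotated_90)`` record makes normalised pill
coordinates invertible back to crop coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.restoration import inpaint_biharmonic
from skimage.transform import resize

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import ImageTooSmallError, InvalidParameterError
from .imgfilters import clahe_equalize, unsharp_sharpen

__all__ = ["PreprocessedImage", "preprocess", "fill_reflections"]


@dataclass(frozen=True)
class PreprocessedImage:
    """Normalised blister crop: HSV channels plus the geometry record.

    ``hue``, ``saturation`` and ``value`` are CLAHE-enhanced [0, 1]
    channels of identical shape with height >= width and long edge
    1000 px; ``value`` is additionally reflection-filled and sharpened.
    ``scale_factor`` is the crop -> normalised scaling; ``rotated_90``
    records whether a 90 deg counter-clockwise rotation was applied
    after scaling.
    """

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray
    scale_factor: float
    rotated_90: bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.value.shape

    def to_crop_coords(self, row: float, col: float) -> tuple[float, float]:
        """Map a normalised (row, col) back into the original crop."""
        h, w = self.shape
        if self.rotated_90:
            # invert np.rot90 CCW: out[i, j] = in[j, W-1-i]  (in: h x w pre-rotation)
            row, col = col, (h - 1) - row
        return row / self.scale_factor, col / self.scale_factor

    def from_crop_coords(self, row: float, col: float) -> tuple[float, float]:
        """Map a crop (row, col) into normalised coordinates."""
        row, col = row * self.scale_factor, col * self.scale_factor
        if self.rotated_90:
            h, w = self.shape
            row, col = (h - 1) - col, row
        return row, col


def fill_reflections(
    value: np.ndarray, level: float = 0.95
) -> np.ndarray:
    """Replace specular reflections by inward interpolation.

    Every pixel with intensity strictly above ``level`` is treated as a
    reflection and in-filled smoothly from the boundary of its region
    (biharmonic interpolation); all other pixels are returned unchanged.
    If the whole image is above ``level`` there is no boundary to
    interpolate from; the image is returned unchanged with a warning.
    """
    value = np.asarray(value, dtype=np.float64)
    if value.ndim != 2:
        raise InvalidParameterError("value channel must be 2-D")
    mask = value > level
    if not mask.any():
        return value.copy()
    if mask.all():
        warnings.warn("entire channel above reflection level; nothing to interpolate from")
        return value.copy()
    filled = inpaint_biharmonic(value, mask)
    out = value.copy()
    out[mask] = np.clip(filled[mask], 0.0, 1.0)
    return out


def _normalized_shape(h: int, w: int, long_edge: int) -> tuple[int, int]:
    if h >= w:
        return long_edge, max(1, round(w * long_edge / h))
    return max(1, round(h * long_edge / w)), long_edge


def preprocess(
    crop_img: np.ndarray, config: PipelineConfig = DEFAULT_CONFIG
) -> PreprocessedImage:
    """Normalise a cropped blister image into analysis-ready HSV channels.

    Steps, in order: scale the long edge to ``config.norm_long_edge``
    (bicubic); rotate 90 deg counter-clockwise if wider than tall;
    RGB -> HSV; CLAHE on each channel; reflection in-fill on the value
    channel; unsharp sharpening on the value channel.

    Raises
    ------
    ImageTooSmallError
        If the crop's long edge is below ``config.min_crop_long_edge``.
    """
    crop_img = np.asarray(crop_img, dtype=np.float64)
    if crop_img.ndim == 2:
        crop_img = np.stack([crop_img] * 3, axis=-1)
    if crop_img.ndim != 3 or crop_img.shape[2] != 3 or crop_img.size == 0:
        raise InvalidParameterError("crop must be an RGB image")
    h, w = crop_img.shape[:2]
    if max(h, w) < config.min_crop_long_edge:
        raise ImageTooSmallError(
            f"crop long edge {max(h, w)} px below minimum {config.min_crop_long_edge}"
        )

    nh, nw = _normalized_shape(h, w, config.norm_long_edge)
    scale_factor = max(nh, nw) / max(h, w)
    scaled = resize(
        crop_img, (nh, nw), order=3, anti_aliasing=(scale_factor < 1.0), preserve_range=True
    )
    scaled = np.clip(scaled, 0.0, 1.0)

    rotated_90 = nw > nh
    if rotated_90:
        scaled = np.rot90(scaled, k=1)

    hsv = rgb2hsv(scaled)
    hue = clahe_equalize(hsv[..., 0], config.clahe_tiles, config.clahe_clip)
    saturation = clahe_equalize(hsv[..., 1], config.clahe_tiles, config.clahe_clip)
    value = clahe_equalize(hsv[..., 2], config.clahe_tiles, config.clahe_clip)
    value = fill_reflections(value, config.reflection_level)
    value = unsharp_sharpen(value, config.sharpen_radius, config.sharpen_strength)

    return PreprocessedImage(
        hue=hue,
        saturation=saturation,
        value=value,
        scale_factor=scale_factor,
        rotated_90=rotated_90,
    )
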