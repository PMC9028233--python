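"""Seeded synthetic blister photographs with ground truth.

The generator renders the image features the pipeline keys on, without
attempting photo-realism:

* a flat (or cluttered) background clearly separated from the blister
  body, so heterogeneity-based localisation has something to find;
* a regular pocket grid on a rounded-corner blister body, in two styles:
  ``gray`` (opaque gray cover: smooth dome with a strong circular rim
  edge) and ``transparent`` (a coloured pill disk visible under a faint
  cover, with a softer rim);
* *taken* pockets rendered as collapsed: the rim is broken into arcs
  (raising the circle-edge ratio) and the interior carries a crumple
  texture of oriented sinusoidal creases plus speckle (raising the 9x9
  local standard deviation) — the deformation signal is stronger for the
  gray style, mirroring how deformations show up much more clearly on
  opaque foil;
* optional near-saturated specular reflections, mild Gaussian blur and
  sensor noise.

Rendering is purely deterministic for a fixed seed; sequences reuse the
blister's appearance and re-randomise only photometric nuisances via
per-frame sub-seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .blister_detect import BoundingBox
from .errors import InvalidSpecError

__all__ = ["BlisterSpec", "GroundTruth", "generate_blister", "generate_sequence"]

# geometry constants, in units of the pocket radius
_PITCH = 2.6          # center-to-center pocket spacing
_GRID_MARGIN = 1.0    # grid edge to blister edge, beyond the pocket radius
_CORNER = 0.3         # blister corner radius


@dataclass(frozen=True)
class BlisterSpec:
    """Parameters of one synthetic blister photograph.

    ``taken`` lists emptied pocket indices (row-major over the grid).
    ``odd_layout`` drops the last pocket of the grid, producing the
    asymmetric last column typical of odd pill counts.  ``pocket_radius``
    is in generated-image pixels; with the default geometry the radius
    after 1000-px normalisation depends only on the grid shape and stays
    inside the Hough band for 3-7 rows.
    """

    n_rows: int = 5
    n_cols: int = 2
    odd_layout: bool = False
    pocket_radius: float = 55.0
    style: str = "gray"  # "gray" | "transparent"
    taken: frozenset[int] = field(default_factory=frozenset)
    pill_color: tuple[float, float, float] = (0.82, 0.55, 0.50)
    reflection_rate: float = 0.10
    blur_sigma: float = 0.8
    noise_sigma: float = 0.008
    background: str = "flat"  # "flat" | "cluttered"
    bg_margin: float = 0.15
    seed: int = 0

    @property
    def n_pockets(self) -> int:
        return self.n_rows * self.n_cols - (1 if self.odd_layout else 0)


@dataclass(frozen=True)
class GroundTruth:
    """Rendering ground truth in generated-image coordinates."""

    pocket_centers: tuple[tuple[float, float], ...]
    taken: frozenset[int]
    blister_box: BoundingBox


def _validate(spec: BlisterSpec) -> None:
    if spec.n_rows < 1 or spec.n_cols < 1 or spec.n_pockets < 1:
        raise InvalidSpecError("grid must contain at least one pocket")
    if spec.pocket_radius < 8:
        raise InvalidSpecError("pocket radius too small to render")
    if _PITCH * spec.pocket_radius < 2 * spec.pocket_radius + 4:
        raise InvalidSpecError("pockets overlap")
    if spec.style not in ("gray", "transparent"):
        raise InvalidSpecError(f"unknown style {spec.style!r}")
    if spec.background not in ("flat", "cluttered"):
        raise InvalidSpecError(f"unknown background {spec.background!r}")
    bad = [i for i in spec.taken if not (0 <= i < spec.n_pockets)]
    if bad:
        raise InvalidSpecError(f"taken indices out of range: {bad}")


def _rounded_rect_mask(
    shape: tuple[int, int], box: BoundingBox, corner: float
) -> np.ndarray:
    rr, cc = np.ogrid[0 : shape[0], 0 : shape[1]]
    t, l = box.top, box.left
    b, r = box.bottom - 1, box.right - 1
    inside = (rr >= t) & (rr <= b) & (cc >= l) & (cc <= r)
    # carve the four corners outside the corner circles
    for cy, cx in ((t + corner, l + corner), (t + corner, r - corner),
                   (b - corner, l + corner), (b - corner, r - corner)):
        corner_zone = (np.abs(rr - cy) <= corner) & (np.abs(cc - cx) <= corner)
        near = ((rr - cy) ** 2 + (cc - cx) ** 2) <= corner**2
        outside_band = (
            ((rr < t + corner) | (rr > b - corner))
            & ((cc < l + corner) | (cc > r - corner))
        )
        inside &= ~(corner_zone & outside_band & ~near)
    return inside


def _clutter(canvas: np.ndarray, rng: np.random.Generator) -> None:
    """Random rectangles and line segments emulating desk/hand clutter."""
    h, w = canvas.shape[:2]
    for _ in range(rng.integers(10, 18)):
        rh, rw = rng.integers(h // 12, h // 3), rng.integers(w // 12, w // 3)
        r0 = rng.integers(0, max(1, h - rh))
        c0 = rng.integers(0, max(1, w - rw))
        canvas[r0 : r0 + rh, c0 : c0 + rw] += rng.uniform(-0.2, 0.25)
    for _ in range(rng.integers(6, 12)):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        length = rng.integers(min(h, w) // 6, min(h, w) // 2)
        ang = rng.uniform(0, np.pi)
        rr = np.clip(np.round(r0 + np.arange(length) * np.sin(ang)).astype(int), 0, h - 1)
        cc = np.clip(np.round(c0 + np.arange(length) * np.cos(ang)).astype(int), 0, w - 1)
        canvas[rr, cc] += rng.uniform(-0.3, 0.3)


def _angular_gap_mask(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multiplier in [0, 1] deleting 2-4 random arcs from a pocket rim."""
    mask = np.ones_like(theta)
    for _ in range(rng.integers(2, 5)):
        center = rng.uniform(-np.pi, np.pi)
        half = np.deg2rad(rng.uniform(12.0, 26.0))
        diff = np.angle(np.exp(1j * (theta - center)))
        mask[np.abs(diff) < half] = 0.0
    return mask


def _crease_texture(
    dr: np.ndarray, dc: np.ndarray, amp: float, rng: np.random.Generator
) -> np.ndarray:
    """Oriented sinusoidal creases plus blurred speckle."""
    tex = np.zeros_like(dr, dtype=np.float64)
    for _ in range(4):
        ang = rng.uniform(0, np.pi)
        lam = rng.uniform(8.0, 18.0)
        phase = rng.uniform(0, 2 * np.pi)
        tex += amp * np.sin(2 * np.pi * (dr * np.sin(ang) + dc * np.cos(ang)) / lam + phase)
    speckle = ndi.gaussian_filter(rng.normal(0.0, 1.0, dr.shape), 1.2)
    tex += amp * speckle
    return tex


def _pocket_grid(spec: BlisterSpec) -> tuple[list[tuple[float, float]], float, float]:
    """Pocket centers relative to the blister top-left corner, plus body size."""
    R = spec.pocket_radius
    pitch = _PITCH * R
    inner = (_GRID_MARGIN + 1.0) * R  # blister edge to first pocket center
    bh = (spec.n_rows - 1) * pitch + 2 * inner
    bw = (spec.n_cols - 1) * pitch + 2 * inner
    centers = []
    for i in range(spec.n_rows):
        for j in range(spec.n_cols):
            if spec.odd_layout and i == spec.n_rows - 1 and j == spec.n_cols - 1:
                continue
            centers.append((inner + i * pitch, inner + j * pitch))
    return centers, bh, bw


def generate_blister(
    spec: BlisterSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic blister photograph.

    Returns an RGB float image in [0, 1] and its :class:`GroundTruth`.
    Deterministic: the same spec (and seed) renders bit-identical output.
    """
    _validate(spec)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    R = spec.pocket_radius
    centers_rel, bh, bw = _pocket_grid(spec)

    margin = spec.bg_margin * max(bh, bw)
    top = int(round(margin * (0.6 + 0.8 * rng.random())))
    left = int(round(margin * (0.6 + 0.8 * rng.random())))
    H = int(round(bh + top + margin * (0.6 + 0.8 * rng.random())))
    W = int(round(bw + left + margin * (0.6 + 0.8 * rng.random())))
    box = BoundingBox(top=top, left=left, height=int(round(bh)), width=int(round(bw)))

    gray_style = spec.style == "gray"
    bg_color = np.array([0.30, 0.29, 0.28])
    body_color = np.array([0.55, 0.55, 0.56]) if gray_style else np.array([0.62, 0.63, 0.64])

    canvas = np.empty((H, W, 3), dtype=np.float64)
    canvas[:] = bg_color
    # gentle global illumination gradient
    ang = rng.uniform(0, 2 * np.pi)
    rr_f, cc_f = np.mgrid[0:H, 0:W].astype(np.float64)
    grad = 0.02 * ((rr_f / H) * np.sin(ang) + (cc_f / W) * np.cos(ang))
    canvas += grad[..., None]
    if spec.background == "cluttered":
        lum = canvas[..., 0].copy()
        _clutter(lum, rng)
        delta = lum - canvas[..., 0]
        canvas += delta[..., None]

    body = _rounded_rect_mask((H, W), box, _CORNER * R)
    canvas[body] = body_color + grad[body, None] * 1.5

    centers_abs = [(top + r, left + c) for r, c in centers_rel]
    reflections: list[tuple[float, float, float, float, float]] = []

    for idx, (cy, cx) in enumerate(centers_abs):
        is_taken = idx in spec.taken
        # local patch around the pocket
        r0, r1 = int(cy - 1.3 * R), int(cy + 1.3 * R) + 1
        c0, c1 = int(cx - 1.3 * R), int(cx + 1.3 * R) + 1
        pr, pc = np.mgrid[r0:r1, c0:c1].astype(np.float64)
        dr, dc = pr - cy, pc - cx
        d = np.hypot(dr, dc)
        theta = np.arctan2(dr, dc)
        patch = np.zeros(d.shape, dtype=np.float64)

        rim_depth = 0.28 if gray_style else 0.14
        rim = np.exp(-(((d - R) / 1.2) ** 2))
        if is_taken:
            rim = rim * _angular_gap_mask(theta, rng)
            # slight radial wobble of the remaining rim
            wobble = 1.5 * np.sin(3 * theta + rng.uniform(0, 2 * np.pi))
            rim = np.maximum(rim, np.exp(-(((d - R - wobble) / 1.2) ** 2)) * 0.7)
        patch -= rim_depth * rim

        window = np.clip((R - 1.5 - d) / (0.15 * R), 0.0, 1.0)
        if not is_taken:
            dome = np.sqrt(np.clip(1.0 - (d / R) ** 2, 0.0, None))
            if gray_style:
                patch += 0.16 * dome
            else:
                patch += 0.05 * dome  # faint cover sheen
        else:
            patch -= 0.04 * window  # collapsed foil sits lower
            amp = 0.05 if gray_style else 0.03
            patch += _crease_texture(dr, dc, amp, rng) * window

        canvas[r0:r1, c0:c1] += patch[..., None]
        if not gray_style and not is_taken:
            # coloured pill disk showing through the transparent cover
            pill = np.clip((0.78 * R - d) / 2.0, 0.0, 1.0)
            base = canvas[r0:r1, c0:c1]
            tint = np.asarray(spec.pill_color)
            canvas[r0:r1, c0:c1] = base * (1 - pill[..., None]) + (
                tint + 0.10 * np.sqrt(np.clip(1 - (d / R) ** 2, 0, None))[..., None]
            ) * pill[..., None]

        if rng.random() < spec.reflection_rate:
            off_r = rng.uniform(-0.45, 0.45) * R
            off_c = rng.uniform(-0.45, 0.45) * R
            reflections.append(
                (cy + off_r, cx + off_c, rng.uniform(0.10, 0.16) * R,
                 rng.uniform(0.20, 0.30) * R, rng.uniform(0, np.pi))
            )

    canvas = ndi.gaussian_filter(canvas, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    # specular reflections stay near-saturated: paint after the blur
    for cy, cx, a, b, phi in reflections:
        r0, r1 = int(cy - b) - 1, int(cy + b) + 2
        c0, c1 = int(cx - b) - 1, int(cx + b) + 2
        pr, pc = np.mgrid[r0:r1, c0:c1].astype(np.float64)
        dr, dc = pr - cy, pc - cx
        u = dr * np.cos(phi) + dc * np.sin(phi)
        v = -dr * np.sin(phi) + dc * np.cos(phi)
        ell = (u / a) ** 2 + (v / b) ** 2
        spot = np.clip(1.2 - ell, 0.0, 1.0)
        region = canvas[r0:r1, c0:c1]
        canvas[r0:r1, c0:c1] = np.maximum(region, 0.985 * np.minimum(spot * 4, 1.0)[..., None])

    canvas += rng.normal(0.0, spec.noise_sigma, canvas.shape)
    np.clip(canvas, 0.0, 1.0, out=canvas)

    truth = GroundTruth(
        pocket_centers=tuple((float(r), float(c)) for r, c in centers_abs),
        taken=frozenset(spec.taken),
        blister_box=box,
    )
    return canvas, truth


def generate_sequence(
    spec: BlisterSpec, taken_schedule: list[set[int] | frozenset[int]]
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Render a sequence of states of the same blister.

    The first schedule entry must be empty (the full blister used for
    registration).  The blister geometry and colours are identical in
    every frame; photometric nuisances (illumination direction, crumple
    textures, reflections, noise) are re-randomised per frame under
    sub-seeds derived from the master seed, so the full sequence is
    reproducible.
    """
    if len(taken_schedule) == 0 or len(taken_schedule[0]) != 0:
        raise InvalidSpecError("schedule must start with the full blister (empty taken set)")
    frames = []
    for i, taken in enumerate(taken_schedule):
        frame_spec = replace(spec, taken=frozenset(taken))
        _validate(frame_spec)
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(i,)))
        # frame rng drives only nuisances; geometry comes from the spec fields
        frames.append(generate_blister(frame_spec, rng=rng))
    return frames
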