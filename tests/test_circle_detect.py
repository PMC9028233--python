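"""Circle Hough Transform and per-circle feature tests."""

import numpy as np
import pytest
from skimage.draw import circle_perimeter

from blistercount.circle_detect import (
    DetectedCircle,
    circle_edge_ratio,
    hough_accumulator,
    hough_circles,
    local_std_mean,
)
from blistercount.errors import InvalidParameterError


def render_rings(shape, rings, gaps=None, rng=None):
    """Binary edge image with ideal one-pixel rings at (row, col, radius)."""
    edges = np.zeros(shape, dtype=bool)
    for i, (r, c, rad) in enumerate(rings):
        rr, cc = circle_perimeter(r, c, rad, shape=shape)
        if gaps and gaps[i] > 0 and rng is not None:
            keep = rng.random(len(rr)) >= gaps[i]
            rr, cc = rr[keep], cc[keep]
        edges[rr, cc] = True
    return edges


def test_empty_edge_image_gives_no_circles():
    assert hough_circles(np.zeros((200, 200), bool)) == []


def test_single_ring_detected_accurately():
    edges = render_rings((400, 500), [(200, 300, 60)])
    circles = hough_circles(edges)
    assert len(circles) == 1
    c = circles[0]
    assert abs(c.center_row - 200) <= 2 and abs(c.center_col - 300) <= 2
    assert abs(c.radius - 60) <= 3
    assert c.metric > 0.5


def test_accumulator_agrees_with_skimage_reference():
    # independent cross-check: drawing-based accumulator vs FFT convolution
    from skimage.transform import hough_circle as skimage_hough

    rng = np.random.default_rng(3)
    edges = render_rings((160, 160), [(80, 70, 40)])
    edges |= rng.random(edges.shape) < 0.02
    radii = np.arange(30, 61, 5)
    ours = hough_accumulator(edges, radii)
    theirs = skimage_hough(edges, radii, normalize=True)
    assert np.allclose(ours, theirs, atol=2e-2)


def test_small_radius_rings_outside_band_excluded():
    edges = render_rings((300, 300), [(150, 150, 20)])
    assert hough_circles(edges, rmin=30, rmax=130) == []


def test_multiple_rings_all_found():
    # ideal one-pixel rings, odd radii included (they sit off the step-2
    # radius grid and score ~0.5, still above the default threshold)
    rings = [(80, 80, 35), (80, 280, 60), (260, 80, 90), (280, 300, 50)]
    edges = render_rings((400, 400), rings)
    circles = hough_circles(edges)
    assert len(circles) == len(rings)
    for r, c, rad in rings:
        best = min(circles, key=lambda d: (d.center_row - r) ** 2 + (d.center_col - c) ** 2)
        assert np.hypot(best.center_row - r, best.center_col - c) <= 3
        assert abs(best.radius - rad) <= 3


def test_no_spurious_circles_on_multi_ring_fixture():
    rings = [(80, 80, 36), (80, 280, 60), (260, 80, 90), (280, 300, 50)]
    edges = render_rings((400, 400), rings)
    circles = hough_circles(edges)
    assert len(circles) == len(rings)  # sidelobes of large rings suppressed


def test_metric_monotone_in_ring_completeness():
    rng = np.random.default_rng(7)
    metrics = []
    for gap in (0.0, 0.2, 0.4, 0.6):
        edges = render_rings((300, 300), [(150, 150, 60)], gaps=[gap], rng=rng)
        circles = hough_circles(edges, sensitivity=0.9)
        assert circles, f"ring with gap {gap} not detected"
        metrics.append(circles[0].metric)
    assert all(a >= b - 0.02 for a, b in zip(metrics, metrics[1:]))


def test_rotation_equivariance_for_quarter_turns():
    edges = render_rings((300, 400), [(100, 250, 44)])
    base = hough_circles(edges)
    rot = hough_circles(np.rot90(edges).copy())
    assert len(base) == len(rot) == 1
    b, r = base[0], rot[0]
    # np.rot90 maps (row, col) -> (W-1-col, row)
    assert abs(r.center_row - (400 - 1 - b.center_col)) <= 1
    assert abs(r.center_col - b.center_row) <= 1
    assert abs(r.radius - b.radius) <= 2
    assert abs(r.metric - b.metric) <= 0.05


def test_invalid_parameters_rejected():
    edges = np.zeros((50, 50), bool)
    with pytest.raises(InvalidParameterError):
        hough_circles(edges, sensitivity=1.5)
    with pytest.raises(InvalidParameterError):
        hough_circles(edges, rmin=50, rmax=40)


def test_circle_edge_ratio_extremes_and_ring():
    circle = DetectedCircle(center_row=100, center_col=100, radius=50, metric=1.0)
    assert circle_edge_ratio(circle, np.zeros((200, 200), bool)) == 0.0
    assert circle_edge_ratio(circle, np.ones((200, 200), bool)) == 1.0
    for rad in (30, 70, 130):
        big = DetectedCircle(center_row=200, center_col=200, radius=rad, metric=1.0)
        edges = render_rings((400, 400), [(200, 200, rad)])
        cer = circle_edge_ratio(big, edges)
        assert cer == pytest.approx(2.0 / rad, rel=0.2)


def test_circle_edge_ratio_clips_out_of_bounds_circles():
    circle = DetectedCircle(center_row=5, center_col=5, radius=30, metric=1.0)
    edges = np.ones((60, 60), bool)
    assert circle_edge_ratio(circle, edges) == 1.0  # only in-bounds pixels counted


def test_local_std_mean_constant_texture_and_determinism(rng):
    flat = np.full((300, 300), 0.5)
    circle = DetectedCircle(center_row=150, center_col=150, radius=60, metric=1.0)
    assert local_std_mean(circle, flat) == pytest.approx(0.0, abs=1e-12)

    textured = np.full((300, 600), 0.5)
    noise = rng.normal(0, 0.1, textured.shape)
    textured = np.clip(textured + noise, 0, 1)
    c1 = DetectedCircle(center_row=150, center_col=150, radius=60, metric=1.0)
    mean1 = local_std_mean(c1, textured)
    assert 0.05 <= mean1 <= 0.15
    # determinism: same circle measured twice
    assert local_std_mean(c1, textured) == mean1
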