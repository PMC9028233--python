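"""Counting-mode tests: matching, classification, orientation, aggregates."""

import numpy as np
import pytest

from blistercount.blister_detect import crop
from blistercount.circle_detect import DetectedCircle
from blistercount.counting import (
    classify_pocket,
    count,
    disambiguate_orientation,
    match_circles,
)
from blistercount.errors import IncompatibleReferenceError
from blistercount.preprocess import preprocess
from blistercount.registration import BlisterReference, register
from blistercount.synthetic import BlisterSpec, generate_sequence


def make_ref(centers, mean_radius=60.0, h=1000, w=600):
    return BlisterReference(
        blister_id="t",
        pill_centers=tuple(centers),
        mean_radius=mean_radius,
        mean_circle_edge_ratio=0.1,
        mean_local_std=0.05,
        pill_count=len(centers),
        image_height=h,
        image_width=w,
    )


def circle(row, col, radius=60.0, metric=0.9):
    return DetectedCircle(center_row=row, center_col=col, radius=radius, metric=metric)


class TestMatching:
    def test_identity_matching(self):
        centers = [(100.0, 100.0), (300.0, 100.0), (500.0, 100.0)]
        ref = make_ref(centers)
        circles = [circle(r, c) for r, c in centers]
        matches = match_circles(ref, circles)
        assert all(m is not None for m in matches)
        assert [(m.center_row, m.center_col) for m in matches] == centers

    def test_circle_beyond_proximity_is_absent(self):
        ref = make_ref([(100.0, 100.0)], mean_radius=60.0)
        # proximity limit is 60 + 10 = 70
        assert match_circles(ref, [circle(100.0, 171.0)]) == [None]
        assert match_circles(ref, [circle(100.0, 170.0)])[0] is not None

    def test_equal_distance_candidates_choose_smaller_radius_deviation(self):
        ref = make_ref([(100.0, 100.0)], mean_radius=60.0)
        a = circle(100.0, 140.0, radius=58.0)
        b = circle(100.0, 60.0, radius=70.0)
        m = match_circles(ref, [b, a])
        assert m[0].radius == 58.0

    def test_one_to_one_greedy_assignment(self):
        # one circle sits between two reference pockets: it may serve one only
        ref = make_ref([(100.0, 100.0), (100.0, 200.0)], mean_radius=60.0)
        shared = circle(100.0, 130.0)
        m = match_circles(ref, [shared])
        assert sum(x is not None for x in m) == 1
        assert m[0] is shared  # closer pocket wins


class TestClassification:
    @pytest.mark.parametrize(
        "d_std, d_cer, label",
        [
            (0.06, 0.0, "taken"),     # large heterogeneity increase alone
            (0.051, 0.0, "taken"),
            (0.03, 0.03, "taken"),    # intermediate band + CER increase
            (0.03, 0.025, "taken"),   # CER bound is inclusive
            (0.03, 0.0249, "present"),
            (0.03, 0.0, "present"),   # intermediate band, CER unchanged
            (0.05, 0.0, "present"),   # std bound is strict
            (0.02, 0.05, "present"),  # band bound is strict
            (0.0, 0.0, "present"),
            (-0.01, 0.1, "present"),
        ],
    )
    def test_threshold_truth_table(self, d_std, d_cer, label):
        assert classify_pocket(d_std, d_cer) == label


class TestOrientation:
    def test_even_count_short_circuits_to_original(self):
        ref = make_ref([(100.0, 100.0), (300.0, 100.0)])
        # pre=None would fail if the rotated branch were evaluated
        assert disambiguate_orientation(None, ref) == "original"

    def test_symmetric_layout_tie_breaks_to_original(self):
        class FakePre:
            shape = (1000, 600)

        centers = [(200.0, 300.0), (500.0, 300.0), (799.0, 299.0)]
        ref = make_ref(centers)
        circles = [circle(r, c) for r, c in centers]
        assert disambiguate_orientation(FakePre(), ref, circles=circles) == "original"

    def test_displaced_odd_layout_picks_rotation(self):
        class FakePre:
            shape = (1000, 600)

        centers = [(200.0, 200.0), (500.0, 200.0), (200.0, 400.0)]
        ref = make_ref(centers)
        # circles at the 180-degree-rotated positions of the reference
        circles = [circle(999 - r, 599 - c) for r, c in centers]
        assert disambiguate_orientation(FakePre(), ref, circles=circles) == "rotated180"


@pytest.fixture(scope="module")
def sequence():
    spec = BlisterSpec(seed=23, style="gray", n_rows=4, n_cols=2)
    schedule = [set(), {1, 6}, {1, 6, 3}]
    frames = generate_sequence(spec, schedule)
    pre0 = preprocess(crop(frames[0][0], frames[0][1].blister_box))
    ref, _ = register(pre0, "seq")
    return frames, pre0, ref


class TestCountPipeline:

    def test_counting_registration_frame_is_all_present(self, sequence):
        frames, pre0, ref = sequence
        res = count(pre0, ref)
        assert res.n_present == ref.pill_count and res.n_taken == 0

    def test_conservation_and_monotone_present(self, sequence):
        frames, _, ref = sequence
        presents = []
        for image, truth in frames:
            res = count(preprocess(crop(image, truth.blister_box)), ref)
            assert res.n_present + res.n_taken == ref.pill_count
            presents.append(res.n_present)
        assert presents == sorted(presents, reverse=True)
        assert presents[1] == ref.pill_count - 2
        assert presents[2] == ref.pill_count - 3

    def test_incompatible_reference_rejected(self, sequence):
        _, pre0, ref = sequence
        from dataclasses import replace

        bad = replace(ref, image_height=2000, pill_centers=ref.pill_centers)
        with pytest.raises(IncompatibleReferenceError):
            count(pre0, bad)


class TestOrientationEndToEnd:
    def test_upside_down_odd_blister_counts_identically(self):
        spec = BlisterSpec(seed=9, style="gray", n_rows=5, n_cols=2, odd_layout=True)
        frames = generate_sequence(spec, [set(), {0, 4}])
        pre0 = preprocess(crop(frames[0][0], frames[0][1].blister_box))
        ref, _ = register(pre0, "odd")
        assert ref.pill_count % 2 == 1
        c1 = crop(frames[1][0], frames[1][1].blister_box)
        upright = count(preprocess(c1), ref)
        upside_down = count(preprocess(np.rot90(c1, k=2).copy()), ref)
        assert upside_down.orientation_used == "rotated180"
        assert [a.label for a in upright.assessments] == [
            a.label for a in upside_down.assessments
        ]
        assert upright.n_present == upside_down.n_present
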