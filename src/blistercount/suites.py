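"""Standard synthetic evaluation batches.

These functions pin down the fixture batches used to evaluate the
pipeline — layouts, styles, schedules and sub-seeding — so the CLI
``eval`` command, the test suite and the reproduction script all measure
the same conditions.  Sizes mirror the validation design at desk scale:
20 full blisters (both styles, >= 200 pills) for registration, 10
gray-style sequences with 100 scored frames for counting, and 50
flat-background photographs for automatic blister detection.
"""

from __future__ import annotations

from collections.abc import Iterator

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .evaluate import (
    EvalReport,
    Fixture,
    eval_blister_detection,
    eval_counting,
    eval_registration,
)
from .synthetic import BlisterSpec, generate_blister, generate_sequence

__all__ = [
    "registration_batch",
    "registration_suite",
    "counting_batches",
    "counting_suite",
    "detection_batch",
    "detection_suite",
]

# grid layouts cycled through the batches: (n_rows, n_cols, odd_layout)
_LAYOUTS = [
    (5, 2, False),
    (4, 2, False),
    (6, 2, False),
    (5, 2, True),
    (4, 3, False),
]


def _sub_seed(master: int, stream: int, index: int) -> int:
    """Deterministic per-fixture seed below 2**31."""
    ss = np.random.SeedSequence(master, spawn_key=(stream, index))
    return int(ss.generate_state(1)[0] % (2**31))


def registration_batch(seed: int, n_images: int = 20) -> Iterator[Fixture]:
    """Full-blister fixtures, half gray / half transparent styles.

    Lazily rendered: frames are generated one at a time so evaluation
    never holds a whole batch of images in memory.
    """
    for i in range(n_images):
        rows, cols, odd = _LAYOUTS[i % len(_LAYOUTS)]
        spec = BlisterSpec(
            n_rows=rows,
            n_cols=cols,
            odd_layout=odd,
            style="gray" if i % 2 == 0 else "transparent",
            pocket_radius=float(45 + 5 * (i % 4)),
            seed=_sub_seed(seed, 1, i),
        )
        image, truth = generate_blister(spec)
        yield (spec, image, truth)


def registration_suite(
    seed: int, n_images: int = 20, config: PipelineConfig = DEFAULT_CONFIG
) -> EvalReport:
    """Registration-mode evaluation on the standard full-blister batch."""
    return eval_registration(registration_batch(seed, n_images), config)


def counting_batches(
    seed: int, n_sequences: int = 10, frames_per_sequence: int = 10
) -> Iterator[list[Fixture]]:
    """Gray-style sequences with growing taken-pill schedules.

    Every sequence starts with the full blister (the registration frame)
    followed by ``frames_per_sequence`` scored frames in which the set of
    emptied pockets grows along a seeded random order; the final frames
    approach (and reach, where the schedule is long enough) the fully
    emptied blister.
    """
    for s in range(n_sequences):
        rows, cols, odd = _LAYOUTS[s % len(_LAYOUTS)]
        spec = BlisterSpec(
            n_rows=rows,
            n_cols=cols,
            odd_layout=odd,
            style="gray",
            pocket_radius=float(45 + 5 * (s % 4)),
            seed=_sub_seed(seed, 2, s),
        )
        order_rng = np.random.default_rng(_sub_seed(seed, 3, s))
        order = order_rng.permutation(spec.n_pockets)
        schedule: list[set[int]] = [set()]
        for k in range(1, frames_per_sequence + 1):
            schedule.append(set(order[: min(k, spec.n_pockets)].tolist()))
        frames = generate_sequence(spec, schedule)
        yield [(spec, img, truth) for img, truth in frames]


def counting_suite(
    seed: int,
    n_sequences: int = 10,
    frames_per_sequence: int = 10,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> EvalReport:
    """Counting-mode evaluation on the standard gray-sequence batch."""
    return eval_counting(counting_batches(seed, n_sequences, frames_per_sequence), config)


def detection_batch(seed: int, n_images: int = 50) -> Iterator[Fixture]:
    """Uncropped flat-background fixtures with varying position and scale."""
    for i in range(n_images):
        rows, cols, odd = _LAYOUTS[i % len(_LAYOUTS)]
        spec = BlisterSpec(
            n_rows=rows,
            n_cols=cols,
            odd_layout=odd,
            style="gray" if i % 2 == 0 else "transparent",
            pocket_radius=float(40 + 3 * (i % 8)),
            background="flat",
            bg_margin=0.12 + 0.03 * (i % 5),
            seed=_sub_seed(seed, 4, i),
        )
        image, truth = generate_blister(spec)
        yield (spec, image, truth)


def detection_suite(
    seed: int, n_images: int = 50, config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[float, int]:
    """Automatic blister detection success fraction on the standard batch."""
    return eval_blister_detection(detection_batch(seed, n_images), config), n_images
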