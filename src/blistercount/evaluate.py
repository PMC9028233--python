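"""Batch evaluation of the pipeline on synthetic fixtures.

Three evaluations mirror the tool's validation design:

* :func:`eval_registration` — full-blister fixtures; counts correctly
  detected pills (an accepted circle center within half the mean radius
  of a ground-truth center) and false positives, per style and total;
* :func:`eval_counting` — blister sequences; registers the first (full)
  frame, counts all later frames, and scores per-pocket present/taken
  labels against ground truth (the registration frame is never scored);
* :func:`eval_blister_detection` — uncropped fixtures; scores automatic
  blister localisation with a geometric proxy for the human judgment:
  the predicted box must contain >= 95% of the true blister area with a
  margin of at most 8% of the blister long edge on every side.

Fixtures are ``(spec, image, truth)`` triples from
:mod:`blistercount.synthetic`.  By default registration/counting crop
with the ground-truth blister box — the synthetic analogue of the
study's manual-crop fallback — so the scores isolate the
registration/counting stages from localisation errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blister_detect import crop, detect_blister
from .config import DEFAULT_CONFIG, PipelineConfig
from .counting import count
from .errors import (
    BlisterCountError,
    InvalidParameterError,
    RegistrationFailedError,
)
from .preprocess import preprocess
from .registration import BlisterReference, register
from .synthetic import BlisterSpec, GroundTruth

__all__ = [
    "EvalRow",
    "EvalReport",
    "eval_registration",
    "eval_counting",
    "eval_blister_detection",
]

Fixture = tuple[BlisterSpec, np.ndarray, GroundTruth]


@dataclass
class EvalRow:
    """One table row of an evaluation report (a style stratum or the total)."""

    n_images: int = 0
    pills_tested: int = 0
    pills_detected: int = 0
    false_positives: int = 0
    present_tested: int = 0
    present_correct: int = 0
    taken_tested: int = 0
    taken_correct: int = 0

    @property
    def detection_pct(self) -> float:
        return 100.0 * self.pills_detected / self.pills_tested if self.pills_tested else 0.0

    @property
    def false_positive_pct(self) -> float:
        total = self.pills_detected + self.false_positives
        return 100.0 * self.false_positives / total if total else 0.0

    @property
    def present_detected_pct(self) -> float:
        return 100.0 * self.present_correct / self.present_tested if self.present_tested else 0.0

    @property
    def taken_detected_pct(self) -> float:
        return 100.0 * self.taken_correct / self.taken_tested if self.taken_tested else 0.0

    @property
    def accuracy_pct(self) -> float:
        tested = self.present_tested + self.taken_tested
        correct = self.present_correct + self.taken_correct
        return 100.0 * correct / tested if tested else 0.0

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "pills_tested": self.pills_tested,
            "pills_detected": self.pills_detected,
            "false_positives": self.false_positives,
            "correct_pill_detection_pct": self.detection_pct,
            "false_positive_pct": self.false_positive_pct,
            "present_tested": self.present_tested,
            "present_correct": self.present_correct,
            "present_detected_pct": self.present_detected_pct,
            "taken_tested": self.taken_tested,
            "taken_correct": self.taken_correct,
            "taken_detected_pct": self.taken_detected_pct,
            "accuracy_pct": self.accuracy_pct,
        }


@dataclass
class EvalReport:
    """Per-style rows plus the pooled total."""

    per_style: dict[str, EvalRow]
    total: EvalRow

    def to_dict(self) -> dict:
        return {
            "per_style": {k: v.to_dict() for k, v in self.per_style.items()},
            "total": self.total.to_dict(),
        }


def _truth_centers_normalized(
    truth: GroundTruth, pre, box
) -> np.ndarray:
    """Ground-truth pocket centers mapped into normalised coordinates."""
    pts = []
    for r, c in truth.pocket_centers:
        pts.append(pre.from_crop_coords(r - box.top, c - box.left))
    return np.array(pts)


def _register_fixture(
    fixture: Fixture, config: PipelineConfig
) -> tuple[BlisterReference, object, np.ndarray]:
    """Crop (ground-truth box), preprocess and register one full blister."""
    spec, image, truth = fixture
    cropped = crop(image, truth.blister_box)
    pre = preprocess(cropped, config)
    ref, _ = register(pre, blister_id=f"synthetic-{spec.seed}", config=config)
    true_norm = _truth_centers_normalized(truth, pre, truth.blister_box)
    return ref, pre, true_norm


def eval_registration(
    batch, config: PipelineConfig = DEFAULT_CONFIG
) -> EvalReport:
    """Score registration-mode pill detection on full-blister fixtures.

    ``batch`` may be any iterable of fixtures; frames are consumed one
    at a time.
    """
    rows: dict[str, EvalRow] = {}
    total = EvalRow()
    for fixture in batch:
        spec, image, truth = fixture
        if truth.taken:
            raise InvalidParameterError("registration fixtures must be full blisters")
        row = rows.setdefault(spec.style, EvalRow())
        row.n_images += 1
        total.n_images += 1
        n_true = len(truth.pocket_centers)
        row.pills_tested += n_true
        total.pills_tested += n_true
        try:
            ref, pre, true_norm = _register_fixture(fixture, config)
        except (RegistrationFailedError, BlisterCountError):
            continue
        tol = ref.mean_radius / 2.0
        claimed = np.zeros(len(true_norm), dtype=bool)
        detected = 0
        false_pos = 0
        for cr, cc in ref.pill_centers:
            d = np.linalg.norm(true_norm - np.array([cr, cc]), axis=1)
            j = int(np.argmin(d))
            if d[j] <= tol and not claimed[j]:
                claimed[j] = True
                detected += 1
            else:
                false_pos += 1
        row.pills_detected += detected
        row.false_positives += false_pos
        total.pills_detected += detected
        total.false_positives += false_pos
    if total.n_images == 0:
        raise InvalidParameterError("empty fixture batch")
    return EvalReport(per_style=rows, total=total)


def eval_counting(
    sequences, config: PipelineConfig = DEFAULT_CONFIG
) -> EvalReport:
    """Score counting-mode labels on blister sequences.

    Each sequence's first frame must be the full blister; it provides the
    reference and is excluded from scoring.  ``sequences`` may be any
    iterable of frame lists; sequences are consumed one at a time.
    """
    rows: dict[str, EvalRow] = {}
    total = EvalRow()
    n_sequences = 0
    for seq in sequences:
        n_sequences += 1
        if not seq:
            raise InvalidParameterError("empty sequence")
        first_spec, _, first_truth = seq[0]
        if first_truth.taken:
            raise InvalidParameterError("sequence must start with a full blister frame")
        ref, pre0, true_norm = _register_fixture(seq[0], config)
        # reference index -> ground-truth pocket index, by nearest center
        ref_to_truth = []
        for cr, cc in ref.pill_centers:
            d = np.linalg.norm(true_norm - np.array([cr, cc]), axis=1)
            j = int(np.argmin(d))
            ref_to_truth.append(j if d[j] <= ref.mean_radius / 2.0 else None)

        for spec, image, truth in seq[1:]:
            row = rows.setdefault(spec.style, EvalRow())
            row.n_images += 1
            total.n_images += 1
            cropped = crop(image, truth.blister_box)
            pre = preprocess(cropped, config)
            result = count(pre, ref, config)
            for assessment in result.assessments:
                j = ref_to_truth[assessment.reference_index]
                if j is None:
                    continue
                truly_taken = j in truth.taken
                correct = (assessment.label == "taken") == truly_taken
                for r in (row, total):
                    if truly_taken:
                        r.taken_tested += 1
                        r.taken_correct += int(correct)
                    else:
                        r.present_tested += 1
                        r.present_correct += int(correct)
    if n_sequences == 0:
        raise InvalidParameterError("empty sequence batch")
    return EvalReport(per_style=rows, total=total)


def eval_blister_detection(
    batch,
    config: PipelineConfig = DEFAULT_CONFIG,
    margin_frac: float = 0.08,
    coverage: float = 0.95,
) -> float:
    """Fraction of fixtures where automatic localisation succeeds.

    Success: the predicted box covers at least ``coverage`` of the true
    blister box area and overhangs it by at most ``margin_frac`` of the
    blister long edge on every side.  ``batch`` may be any iterable.
    """
    successes = 0
    n_total = 0
    for spec, image, truth in batch:
        n_total += 1
        tb = truth.blister_box
        try:
            pb = detect_blister(image, config)
        except BlisterCountError:
            continue
        inter_h = max(0, min(pb.bottom, tb.bottom) - max(pb.top, tb.top))
        inter_w = max(0, min(pb.right, tb.right) - max(pb.left, tb.left))
        covered = (inter_h * inter_w) / (tb.height * tb.width)
        margin_limit = margin_frac * max(tb.height, tb.width)
        margins = (
            tb.top - pb.top,
            pb.bottom - tb.bottom,
            tb.left - pb.left,
            pb.right - tb.right,
        )
        if covered >= coverage and all(m <= margin_limit for m in margins):
            successes += 1
    if n_total == 0:
        raise InvalidParameterError("empty fixture batch")
    return successes / n_total
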