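"""Segmentation evaluation: Dice score, outcome classification, accuracy.

Per-structure evaluation treats "was the anatomy correctly predicted" as a
classification task on top of the Dice overlap between the predicted and
annotated binary masks:

* TP -- Dice in [0.5, 1] (inclusive lower bound),
* TN -- annotated and predicted areas both zero,
* FN -- annotated area non-zero but Dice below 0.5 (a missing prediction
  counts as Dice 0),
* FP -- non-zero predicted area without a corresponding annotation.

Accuracy is then (TP + TN) / (TP + TN + FN + FP).  Reports aggregate these
per structure, average per plane over the plane's minimum required
features, and optionally stratify the evaluated frames by ground-truth
quality score (QS), with "above average" conventionally QS >= 6.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .planes import STANDARD_PLANES, PlaneProtocol

#: Conventional "above average" quality-score cutoff.
QS_ABOVE_AVERAGE = 6


class Outcome(str, enum.Enum):
    TP = "TP"
    TN = "TN"
    FN = "FN"
    FP = "FP"


@dataclass(frozen=True)
class DiceOutcome:
    """Dice score and outcome label for one (prediction, annotation) pair."""

    structure: str
    dice: Optional[float]  # None when both masks are empty
    outcome: Outcome


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> None:
    if pred.shape != truth.shape:
        raise ValueError(
            f"mask shape mismatch: {pred.shape} vs {truth.shape}")


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity 2|P∩T| / (|P|+|T|) between two binary masks.

    Undefined (raises) when both masks are empty; that degenerate case is
    routed to TN by :func:`classify_outcome` without going through Dice.
    """

    _check_pair(pred, truth)
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        raise ValueError("Dice is undefined when both masks are empty")
    return 2.0 * int(np.logical_and(p, t).sum()) / denom


def classify_outcome(pred: np.ndarray, truth: np.ndarray,
                     structure: str = "") -> DiceOutcome:
    """Assign the TP/TN/FN/FP label for one structure on one frame."""

    _check_pair(pred, truth)
    p_area = int(np.asarray(pred, dtype=bool).sum())
    t_area = int(np.asarray(truth, dtype=bool).sum())
    if t_area == 0 and p_area == 0:
        return DiceOutcome(structure, None, Outcome.TN)
    if t_area == 0:
        return DiceOutcome(structure, dice(pred, truth), Outcome.FP)
    d = dice(pred, truth) if p_area > 0 else 0.0
    outcome = Outcome.TP if d >= 0.5 else Outcome.FN
    return DiceOutcome(structure, d, outcome)


def accuracy(outcomes) -> float:
    """(TP + TN) / (TP + TN + FN + FP) over a collection of outcomes.

    Accepts an iterable of :class:`DiceOutcome` / :class:`Outcome`, or a
    mapping of outcome label to count.  Counting is exact (rational
    arithmetic) before the final division.
    """

    counts = {o: 0 for o in Outcome}
    if isinstance(outcomes, Mapping):
        for key, n in outcomes.items():
            counts[Outcome(key)] += int(n)
    else:
        for item in outcomes:
            o = item.outcome if isinstance(item, DiceOutcome) else Outcome(item)
            counts[o] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("accuracy of an empty outcome collection")
    frac = Fraction(counts[Outcome.TP] + counts[Outcome.TN], total)
    return float(frac)


# --------------------------------------------------------------------------
# Frame-level evaluation and reporting
# --------------------------------------------------------------------------


@dataclass
class FrameEval:
    """Aligned prediction/annotation masks for one frame.

    ``pred_masks`` and ``true_masks`` map structure names to binary masks;
    a structure absent from either mapping is treated as an empty mask.
    """

    plane: str
    qs_true: int
    pred_masks: Mapping[str, np.ndarray]
    true_masks: Mapping[str, np.ndarray]
    frame_index: int = 0


@dataclass
class AccuracyReport:
    """Per-structure and per-plane accuracy, optionally QS-stratified.

    ``per_structure`` has one row per (plane, structure) with outcome
    counts and accuracy; ``per_plane`` maps plane -> (mean, sd, n_images)
    over that plane's minimum required features, or None for planes with no
    qualifying frames.  ``overall`` averages the available plane means.
    """

    per_structure: pd.DataFrame
    per_plane: Dict[str, Optional[Tuple[float, float, int]]]
    qs_threshold: Optional[int]
    n_images: int

    @property
    def missing_planes(self) -> List[str]:
        return [p for p, v in self.per_plane.items() if v is None]

    @property
    def overall(self) -> float:
        means = [v[0] for v in self.per_plane.values() if v is not None]
        if not means:
            raise ValueError("no plane has qualifying frames")
        return float(np.mean(means))

    def to_frame(self) -> pd.DataFrame:
        return self.per_structure.copy()


def _empty_like(masks: Mapping[str, np.ndarray]) -> np.ndarray:
    any_mask = next(iter(masks.values()))
    return np.zeros_like(np.asarray(any_mask, dtype=bool))


def report(
    frames: Sequence[FrameEval],
    protocol: PlaneProtocol,
    qs_threshold: Optional[int] = None,
) -> AccuracyReport:
    """Accuracy report over evaluated frames.

    Outcomes for a structure aggregate over the frames of that structure's
    own plane only; frames of other planes do not contribute (this avoids
    inflating the TN count with frames where the structure could never
    appear).  With ``qs_threshold`` set, only frames whose ground-truth QS
    is >= the threshold are evaluated; planes left with no qualifying
    frames are reported missing rather than zero.
    """

    if qs_threshold is not None and not 1 <= qs_threshold <= 10:
        raise ValueError("qs_threshold must be in 1..10 or None")

    kept = [f for f in frames
            if qs_threshold is None or f.qs_true >= qs_threshold]

    rows = []
    per_plane: Dict[str, Optional[Tuple[float, float, int]]] = {}
    for plane in STANDARD_PLANES:
        plane_frames = [f for f in kept if f.plane == plane]
        if not plane_frames:
            per_plane[plane] = None
            continue
        struct_acc = []
        for structure in protocol.required(plane):
            counts = {o: 0 for o in Outcome}
            for f in plane_frames:
                truth = f.true_masks.get(structure)
                pred = f.pred_masks.get(structure)
                if truth is None and pred is None:
                    counts[Outcome.TN] += 1
                    continue
                ref = truth if truth is not None else pred
                truth = truth if truth is not None else np.zeros_like(
                    np.asarray(ref, dtype=bool))
                pred = pred if pred is not None else np.zeros_like(
                    np.asarray(ref, dtype=bool))
                counts[classify_outcome(pred, truth).outcome] += 1
            acc = accuracy(counts)
            struct_acc.append(acc)
            rows.append({
                "plane": plane, "structure": structure,
                "n": len(plane_frames),
                "TP": counts[Outcome.TP], "TN": counts[Outcome.TN],
                "FN": counts[Outcome.FN], "FP": counts[Outcome.FP],
                "accuracy": acc,
            })
        mean = float(np.mean(struct_acc))
        sd = float(np.std(struct_acc, ddof=0))
        per_plane[plane] = (mean, sd, len(plane_frames))

    per_structure = pd.DataFrame(
        rows, columns=["plane", "structure", "n", "TP", "TN", "FN", "FP",
                       "accuracy"])
    if not per_structure.empty:
        per_structure["plane_avg"] = per_structure["plane"].map(
            lambda p: per_plane[p][0] if per_plane[p] else math.nan)
        per_structure["plane_sd"] = per_structure["plane"].map(
            lambda p: per_plane[p][1] if per_plane[p] else math.nan)

    return AccuracyReport(
        per_structure=per_structure,
        per_plane=per_plane,
        qs_threshold=qs_threshold,
        n_images=len(kept),
    )


def false_positive_count(frames: Sequence[FrameEval],
                         structures: Iterable[str]) -> int:
    """Total FP outcomes over the given structures on the given frames.

    Intended for non-heart evaluation frames, where every annotation is
    empty and any non-zero predicted area is a false positive.
    """

    n_fp = 0
    for f in frames:
        for s in structures:
            pred = f.pred_masks.get(s)
            truth = f.true_masks.get(s)
            if pred is None:
                continue
            if truth is None:
                truth = np.zeros_like(np.asarray(pred, dtype=bool))
            if classify_outcome(pred, truth).outcome is Outcome.FP:
                n_fp += 1
    return n_fp


def mean_required_dice(frames: Sequence[FrameEval],
                       protocol: PlaneProtocol,
                       qs_threshold: Optional[int] = None) -> float:
    """Mean Dice over required features of heart frames (TN pairs skipped)."""
    vals: List[float] = []
    for f in frames:
        if f.plane not in STANDARD_PLANES:
            continue
        if qs_threshold is not None and f.qs_true < qs_threshold:
            continue
        for s in protocol.required(f.plane):
            truth = f.true_masks.get(s)
            if truth is None or not np.any(truth):
                continue
            pred = f.pred_masks.get(s)
            if pred is None or not np.any(pred):
                vals.append(0.0)
            else:
                vals.append(dice(pred, truth))
    if not vals:
        raise ValueError("no (frame, required-structure) pairs to score")
    return float(np.mean(vals))
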