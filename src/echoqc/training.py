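"""Training on phantom data, including the empty-mask strategy for
non-heart frames.

A segmentation model trained only on heart planes produces false-positive
structure masks on the many non-heart frames of a real scan video; mixing
non-heart frames whose target is an all-empty (all-background) mask into
the training set teaches the network to stay silent off-plane.
``nonheart_fraction`` controls that mix.

Data discipline mirrors patient-level splitting: one :class:`VideoScript`
plays the role of one subject, and train/validation/test splits are made
at the script level so no pseudo-subject contributes frames to more than
one split.

The composite loss is ``w_seg * (per-class soft-Dice + pixelwise
cross-entropy over structures + background) + w_qs * |QS error|``.  The
soft-Dice term is smoothed (constant 1) so an empty target against an
empty prediction contributes zero loss, which the empty-mask strategy
requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import FrameEval, mean_required_dice
from .model import (Network, SegmentationOutput, binarize, output_from_logits,
                    pooled_qs, QS_OFFSET)
from .nn import Adam
from .phantom import (NONHEART, PhantomFrame, PlaneSpec, Segment, VideoScript,
                      default_plane_specs, generate_video, random_degradation)
from .planes import PlaneProtocol, STANDARD_PLANES, default_protocol


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    n_epochs: int = 12
    batch_size: int = 4
    learning_rate: float = 3e-3
    nonheart_fraction: float = 0.3
    seed: int = 0
    loss_weights: Tuple[float, float] = (1.0, 0.1)  # (w_seg, w_qs)

    def __post_init__(self) -> None:
        if self.n_epochs < 1 or self.batch_size < 1 or \
                self.learning_rate <= 0:
            raise ValueError("n_epochs, batch_size, learning_rate must be "
                             "positive")
        if not 0.0 <= self.nonheart_fraction < 1.0:
            raise ValueError("nonheart_fraction must be in [0, 1)")
        w_seg, w_qs = self.loss_weights
        if w_seg < 0 or w_qs < 0 or (w_seg == 0 and w_qs == 0):
            raise ValueError("at least one loss weight must be positive")


# --------------------------------------------------------------------------
# Dataset
# --------------------------------------------------------------------------


@dataclass
class PhantomDataset:
    """Frames generated from scripts, split at the script level."""

    frames: List[PhantomFrame]
    script_ids: np.ndarray  # per-frame pseudo-subject id
    splits: Dict[str, np.ndarray]  # split name -> frame indices
    structure_names: Tuple[str, ...]
    size: Tuple[int, int]

    def split_frames(self, split: str) -> List[PhantomFrame]:
        return [self.frames[i] for i in self.splits[split]]

    def split_script_ids(self, split: str) -> set:
        return {int(self.script_ids[i]) for i in self.splits[split]}

    def tensors(self, split: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(images (N,1,H,W), label maps (N,H,W), qs (N,)) for a split.

        Label maps assign each pixel the index of its structure in
        ``structure_names`` (later structures win on overlap) or the
        background index ``len(structure_names)``.
        """

        frames = self.split_frames(split)
        n = len(frames)
        h, w = self.size
        bg = len(self.structure_names)
        images = np.zeros((n, 1, h, w), dtype=np.float32)
        labels = np.full((n, h, w), bg, dtype=np.int32)
        qs = np.zeros(n, dtype=np.float32)
        index = {name: i for i, name in enumerate(self.structure_names)}
        for k, f in enumerate(frames):
            images[k, 0] = f.image
            qs[k] = f.qs_true
            for name, mask in f.masks.items():
                labels[k][mask] = index[name]
        return images, labels, qs


def make_dataset(
    scripts: Sequence[VideoScript],
    nonheart_fraction: float = 0.3,
    split: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    size: Tuple[int, int] = (64, 64),
    structure_names: Optional[Sequence[str]] = None,
) -> PhantomDataset:
    """Generate frames from scripts and split them subject-wise.

    ``nonheart_fraction`` is the target fraction of NonHeart frames in the
    final collection; extra NonHeart-only scripts are synthesised (seeded)
    to reach it.  NonHeart frames carry all-empty target masks.  Splitting
    is at the script level, stratified so heart and NonHeart scripts both
    appear in every split when present.
    """

    if len(scripts) < 3:
        raise ValueError("need at least 3 scripts to split train/val/test")
    if not math.isclose(sum(split), 1.0, rel_tol=1e-6):
        raise ValueError("split fractions must sum to 1")

    rng = np.random.default_rng(seed)
    scripts = list(scripts)
    specs = default_plane_specs()

    n_heart = sum(s.n_frames for s in scripts)
    if nonheart_fraction > 0:
        target = int(round(nonheart_fraction / (1.0 - nonheart_fraction)
                           * n_heart))
        per_script = max(8, target // max(3, len(scripts) // 3))
        while target > 0:
            n = min(per_script, max(target, 1))
            sched = tuple(random_degradation(rng) for _ in range(n))
            scripts.append(VideoScript(
                segments=(Segment(specs[NONHEART], sched, n),),
                seed=int(rng.integers(0, 2 ** 31))))
            target -= n

    def is_nonheart(s: VideoScript) -> bool:
        return all(seg.plane_spec.plane == NONHEART for seg in s.segments)

    # stratified script-level split
    assignment: Dict[int, str] = {}
    for group in (
        [i for i, s in enumerate(scripts) if not is_nonheart(s)],
        [i for i, s in enumerate(scripts) if is_nonheart(s)],
    ):
        if not group:
            continue
        order = rng.permutation(len(group))
        n = len(group)
        n_val = max(1, int(round(split[1] * n))) if n >= 3 else 0
        n_test = max(1, int(round(split[2] * n))) if n >= 3 else 0
        for pos, j in enumerate(order):
            idx = group[j]
            if pos < n_test:
                assignment[idx] = "test"
            elif pos < n_test + n_val:
                assignment[idx] = "val"
            else:
                assignment[idx] = "train"

    if structure_names is None:
        structure_names = default_protocol().feature_names

    frames: List[PhantomFrame] = []
    script_ids: List[int] = []
    split_indices: Dict[str, List[int]] = {"train": [], "val": [], "test": []}
    for sid, script in enumerate(scripts):
        for f in generate_video(script, size=size):
            split_indices[assignment[sid]].append(len(frames))
            frames.append(f)
            script_ids.append(sid)

    return PhantomDataset(
        frames=frames,
        script_ids=np.asarray(script_ids),
        splits={k: np.asarray(v, dtype=int) for k, v in split_indices.items()},
        structure_names=tuple(structure_names),
        size=(int(size[0]), int(size[1])),
    )


def screening_scripts(
    n_scripts: int,
    frames_per_plane: int = 4,
    seed: int = 0,
    planes: Sequence[str] = STANDARD_PLANES,
) -> List[VideoScript]:
    """Scripts that sweep all standard planes with varied degradation.

    Each script visits every plane once with ``frames_per_plane`` frames
    whose degradations are drawn across the quality range, so the
    resulting dataset covers all planes and QS levels.
    """

    rng = np.random.default_rng(seed)
    specs = default_plane_specs()
    scripts = []
    for _ in range(n_scripts):
        segs = []
        for plane in planes:
            sched = []
            for j in range(frames_per_plane):
                if j == 0:  # guarantee high-QS coverage of every plane
                    sched.append(random_degradation(rng, max_shadow=0.05))
                else:
                    sched.append(random_degradation(rng))
            segs.append(Segment(specs[plane], tuple(sched), frames_per_plane))
        scripts.append(VideoScript(segments=tuple(segs),
                                   seed=int(rng.integers(0, 2 ** 31))))
    return scripts


# --------------------------------------------------------------------------
# Loss
# --------------------------------------------------------------------------

_DICE_SMOOTH = 1.0  # keeps empty-vs-empty soft-Dice loss at zero

#: Cross-entropy weight on structure (non-background) pixels.  Structures
#: cover a small fraction of each frame and split over 28 classes; without
#: upweighting, the 29-way softmax collapses to all-background on small
#: training sets.
_FG_WEIGHT = 15.0

#: Hard-negative scale on all-background (non-heart) frames: each pixel's
#: cross-entropy weight is 1 + scale * (structure probability mass the
#: model currently places there).  Background is abundant and easy on
#: heart frames, but on non-heart frames it *is* the lesson; without
#: extra pressure the empty-mask strategy is drowned out by the heart
#: frames' foreground gradients and false-positive suppression fails to
#: train.  The training loop ramps the scale linearly from 0 to this
#: value over the epochs: early in training structure probabilities are
#: diffuse everywhere, so immediate pressure acts as a blanket
#: background push that stalls segmentation; ramping lets the model
#: learn the anatomy first and then unlearn its false positives.
_HARD_NEGATIVE_SCALE = 6.0


def loss_and_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    qs_true: np.ndarray,
    n_structures: int,
    w_seg: float = 1.0,
    w_qs: float = 0.1,
    hard_negative_scale: float = _HARD_NEGATIVE_SCALE,
) -> Tuple[float, Dict[str, float], np.ndarray]:
    """Composite loss and its gradient w.r.t. the head logits.

    Returns (total, {"seg": ..., "qs": ...}, dlogits).
    """

    n, c, h, w = logits.shape
    n_class = n_structures + 1
    class_logits = logits[:, :n_class]
    z = class_logits - class_logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)  # (N, C, H, W)

    onehot = np.zeros_like(p)
    ni, hi, wi = np.meshgrid(np.arange(n), np.arange(h), np.arange(w),
                             indexing="ij")
    onehot[ni, labels, hi, wi] = 1.0

    # per-pixel CE weight: foreground pixels count _FG_WEIGHT times; on
    # all-background frames, weight follows the model's own false-positive
    # probability mass (treated as constant in the gradient)
    pix_w = np.where(labels < n_structures, _FG_WEIGHT, 1.0)
    all_bg = (labels >= n_structures).all(axis=(1, 2))
    if all_bg.any():
        fp_mass = 1.0 - p[all_bg, n_structures]
        pix_w[all_bg] = 1.0 + hard_negative_scale * fp_mass
    wsum = float(pix_w.sum())
    ce = float(-(np.log(np.maximum(p, 1e-12)) * onehot
                 * pix_w[:, None]).sum() / wsum)
    d_ce = (p - onehot) * pix_w[:, None] / wsum

    # per-image, per-class soft Dice on probabilities.  Only classes present
    # in the frame's target (plus background) contribute: the smoothing
    # already makes empty-vs-empty exact, and suppression of absent classes
    # is the weighted cross-entropy's job -- an extra push-down from every
    # absent class swamps the presence signal on small training sets.
    inter = (p * onehot).sum(axis=(2, 3))  # (N, C)
    psum = p.sum(axis=(2, 3))
    ysum = onehot.sum(axis=(2, 3))
    active = (ysum > 0).astype(p.dtype)  # background is always active
    n_active = active.sum()
    num = 2.0 * inter + _DICE_SMOOTH
    den = psum + ysum + _DICE_SMOOTH
    dice_loss = float((active * (1.0 - num / den)).sum() / n_active)
    # d/dp_i of the above: -(2 y_i den - num) / den^2 per active class
    g = -(2.0 * onehot * den[:, :, None, None] - num[:, :, None, None]) \
        * active[:, :, None, None] / (den[:, :, None, None] ** 2) / n_active
    d_dice = p * (g - (p * g).sum(axis=1, keepdims=True))

    seg_loss = ce + dice_loss

    qs_map = logits[:, n_class]
    qs_pre = qs_map.mean(axis=(1, 2)) + QS_OFFSET
    err = qs_pre - qs_true
    qs_loss = float(np.abs(err).mean())
    d_qs = np.sign(err)[:, None, None] / (n * h * w)

    dlogits = np.zeros_like(logits)
    dlogits[:, :n_class] = w_seg * (d_ce + d_dice)
    dlogits[:, n_class] = w_qs * d_qs

    total = w_seg * seg_loss + w_qs * qs_loss
    return total, {"seg": seg_loss, "qs": qs_loss}, dlogits


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------


@dataclass
class TrainResult:
    """Trained parameters (loaded into the network) plus the metrics log."""

    metrics: pd.DataFrame  # epoch, loss, seg_loss, qs_loss, val_dice, val_qs_mae
    best_epoch: int
    best_score: float


def predict_frames(
    network: Network,
    frames: Sequence[PhantomFrame],
    structure_names: Sequence[str],
    threshold: float = 0.5,
    min_area: int = 0,
    batch_size: int = 16,
) -> List[FrameEval]:
    """Run inference and package aligned prediction/truth masks."""

    evals: List[FrameEval] = []
    s = network.config.n_structures
    for start in range(0, len(frames), batch_size):
        chunk = frames[start:start + batch_size]
        x = np.stack([f.image for f in chunk])[:, None].astype(np.float32)
        logits = network.forward(x, train=False)
        for f, lg in zip(chunk, logits):
            out = output_from_logits(lg, s)
            bz = binarize(out, threshold=threshold, min_area=min_area)
            pred = {name: bz["masks"][i]
                    for i, name in enumerate(structure_names)
                    if bz["present"][i]}
            evals.append(FrameEval(
                plane=f.plane, qs_true=f.qs_true,
                pred_masks=pred, true_masks=f.masks,
                frame_index=f.frame_index))
    return evals


def _validation_metrics(network: Network, dataset: PhantomDataset,
                        protocol: PlaneProtocol) -> Tuple[float, float]:
    frames = dataset.split_frames("val")
    evals = predict_frames(network, frames, dataset.structure_names)
    heart = [f for f in frames if f.plane != NONHEART]
    try:
        val_dice = mean_required_dice(
            [e for e in evals if e.plane != NONHEART], protocol)
    except ValueError:
        val_dice = float("nan")
    x = np.stack([f.image for f in frames])[:, None].astype(np.float32)
    qs_true = np.array([f.qs_true for f in frames], dtype=np.float32)
    preds = []
    for start in range(0, len(frames), 16):
        logits = network.forward(x[start:start + 16], train=False)
        nc = network.config.n_structures + 1
        preds.extend(pooled_qs(lg[nc]) for lg in logits)
    val_qs_mae = float(np.abs(np.asarray(preds) - qs_true).mean())
    return val_dice, val_qs_mae


def train(
    network: Network,
    dataset: PhantomDataset,
    config: TrainConfig,
    protocol: Optional[PlaneProtocol] = None,
    verbose: bool = False,
) -> TrainResult:
    """Train the network; keeps the best-on-validation parameters.

    The selection score is validation mean Dice over required features
    minus a small penalty for QS error (``val_dice - val_qs_mae / 18``),
    so segmentation quality dominates but a collapsing QS head is
    penalised.  Raises :class:`TrainingDiverged` on a non-finite loss.
    """

    protocol = protocol or default_protocol()
    w_seg, w_qs = config.loss_weights
    rng = np.random.default_rng(config.seed)
    opt = Adam(network.params(), lr=config.learning_rate)

    images, labels, qs = dataset.tensors("train")
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty training split")

    rows = []
    best_state = network.state()
    best_score = -np.inf
    best_epoch = -1
    for epoch in range(config.n_epochs):
        order = rng.permutation(n)
        tot = seg = qsl = 0.0
        n_batches = 0
        # hard-negative curriculum: no FP pressure at epoch 0, full at the
        # final epoch (see _HARD_NEGATIVE_SCALE)
        hn_scale = _HARD_NEGATIVE_SCALE * epoch / max(config.n_epochs - 1, 1)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = network.forward(images[idx], train=True)
            loss, parts, dlogits = loss_and_grad(
                logits, labels[idx], qs[idx],
                network.config.n_structures, w_seg, w_qs,
                hard_negative_scale=hn_scale)
            if not math.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}")
            opt.zero_grad()
            network.backward(dlogits)
            opt.step()
            tot += loss
            seg += parts["seg"]
            qsl += parts["qs"]
            n_batches += 1

        val_dice, val_qs_mae = _validation_metrics(network, dataset, protocol)
        score = (0.0 if math.isnan(val_dice) else val_dice) - val_qs_mae / 18.0
        if score > best_score:
            best_score = score
            best_state = network.state()
            best_epoch = epoch
        rows.append({
            "epoch": epoch,
            "loss": tot / n_batches,
            "seg_loss": seg / n_batches,
            "qs_loss": qsl / n_batches,
            "val_dice": val_dice,
            "val_qs_mae": val_qs_mae,
        })
        if verbose:
            print(f"epoch {epoch}: loss {tot / n_batches:.4f} "
                  f"val_dice {val_dice:.3f} val_qs_mae {val_qs_mae:.2f}")

    network.load_state(best_state)
    return TrainResult(metrics=pd.DataFrame(rows), best_epoch=best_epoch,
                       best_score=float(best_score))
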