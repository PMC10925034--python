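"""Auto-capture: stream frames, identify standard planes, keep the best
(highest-QS) frame per plane, and report scan completeness.

During a screening sweep the sonographer moves through planes without
saving most frames; the auto-capture engine watches the model's output for
every frame, assigns the frame to a standard plane when that plane's
minimum required features are all predicted present, and retains the frame
with the highest predicted quality score per plane.  At the end of the
session a completeness report lists captured planes, missing mandatory
planes, and non-mandatory planes captured beyond protocol requirements
(e.g. the sagittal aortic arch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .metrics import FrameEval
from .model import Network, SegmentationOutput, binarize
from .phantom import NONHEART, PhantomFrame
from .planes import PlaneProtocol, STANDARD_PLANES


# --------------------------------------------------------------------------
# Frame-level models (the network, or a ground-truth oracle for testing)
# --------------------------------------------------------------------------


class NetworkModel:
    """Adapter running a trained :class:`Network` on phantom frames."""

    def __init__(self, network: Network, structure_names: Sequence[str]):
        if len(structure_names) != network.config.n_structures:
            raise ValueError("structure_names length must equal "
                             "n_structures")
        self.network = network
        self.structure_names = tuple(structure_names)

    def predict(self, frame: PhantomFrame) -> SegmentationOutput:
        return self.network.predict(frame.image)


class OracleModel:
    """Ground-truth stand-in for the network: emits the frame's own masks
    as probability maps and its true QS as the prediction.  Used to test
    the capture logic independently of any trained weights."""

    def __init__(self, structure_names: Sequence[str]):
        self.structure_names = tuple(structure_names)

    def predict(self, frame: PhantomFrame) -> SegmentationOutput:
        h, w = frame.image.shape
        s = len(self.structure_names)
        maps = np.zeros((s, h, w), dtype=np.float32)
        for i, name in enumerate(self.structure_names):
            if name in frame.masks:
                maps[i] = frame.masks[name].astype(np.float32)
        background = 1.0 - maps.max(axis=0)
        return SegmentationOutput(
            structure_maps=maps,
            background_map=background,
            qs_map=np.full((h, w), frame.qs_true - 5.5, dtype=np.float32),
            qs_pred=float(frame.qs_true),
        )


# --------------------------------------------------------------------------
# Plane assignment
# --------------------------------------------------------------------------


def assign_plane(
    output: SegmentationOutput,
    protocol: PlaneProtocol,
    structure_names: Sequence[str],
    threshold: float = 0.5,
    min_area: int = 0,
) -> str:
    """Assign a frame's output to a standard plane, or NonHeart.

    A plane is *attained* when every one of its minimum required features
    is predicted present (binarised area above ``min_area``).  If several
    planes are attained the one with the highest mean required-feature
    area fraction wins; exact ties fall back to the canonical plane order.
    With no plane attained the frame is NonHeart.
    """

    bz = binarize(output, threshold=threshold, min_area=min_area)
    index = {name: i for i, name in enumerate(structure_names)}
    n_pix = output.background_map.size
    areas = bz["masks"].sum(axis=(1, 2))

    best_plane = NONHEART
    best_score = -1.0
    for plane in STANDARD_PLANES:
        req = protocol.required(plane)
        ids = [index[name] for name in req if name in index]
        if len(ids) != len(req):
            continue
        if not all(bz["present"][i] for i in ids):
            continue
        score = float(np.mean([areas[i] for i in ids])) / n_pix
        if score > best_score:  # strict: ties keep earlier plane order
            best_plane, best_score = plane, score
    return best_plane


# --------------------------------------------------------------------------
# Capture session
# --------------------------------------------------------------------------


@dataclass
class BestFrame:
    frame_index: int
    qs_pred: float
    payload: Optional[PhantomFrame] = None


@dataclass
class CaptureState:
    """Running best-frame record per plane while streaming a video."""

    best: Dict[str, BestFrame] = field(default_factory=dict)
    processed: int = 0
    skipped: int = 0
    skip_log: List[str] = field(default_factory=list)


def ingest_frame(
    frame: PhantomFrame,
    model,
    state: CaptureState,
    protocol: PlaneProtocol,
    threshold: float = 0.5,
    min_area: int = 0,
    keep_payload: bool = True,
) -> CaptureState:
    """Process one streamed frame.

    The stored best frame for the assigned plane is replaced only on a
    strictly higher predicted QS, so ties keep the earlier frame and
    constant-quality segments do not churn.  Malformed frames are skipped
    and logged, never abort the stream.
    """

    try:
        output = model.predict(frame)
        plane = assign_plane(output, protocol, model.structure_names,
                             threshold=threshold, min_area=min_area)
    except Exception as exc:  # noqa: BLE001 - stream robustness by contract
        state.skipped += 1
        state.skip_log.append(
            f"frame {getattr(frame, 'frame_index', '?')}: {exc}")
        return state

    state.processed += 1
    if plane != NONHEART:
        current = state.best.get(plane)
        if current is None or output.qs_pred > current.qs_pred:
            state.best[plane] = BestFrame(
                frame_index=frame.frame_index,
                qs_pred=float(output.qs_pred),
                payload=frame if keep_payload else None,
            )
    return state


@dataclass
class CompletenessReport:
    """End-of-session summary against the scan protocol."""

    captured: Dict[str, BestFrame]
    missing_mandatory: List[str]
    extra_non_mandatory: List[str]
    processed: int
    skipped: int

    def to_dict(self) -> dict:
        return {
            "captured": {
                plane: {"frame_index": bf.frame_index,
                        "qs_pred": bf.qs_pred}
                for plane, bf in self.captured.items()
            },
            "missing_mandatory": list(self.missing_mandatory),
            "extra_non_mandatory": list(self.extra_non_mandatory),
            "processed": self.processed,
            "skipped": self.skipped,
        }


def finalize(state: CaptureState,
             protocol: PlaneProtocol) -> CompletenessReport:
    """Close the session: captured planes, missing mandatory planes, and
    non-mandatory planes captured beyond the protocol."""

    captured = dict(state.best)
    missing = [p for p in protocol.mandatory_planes if p not in captured]
    extra = [p for p in STANDARD_PLANES
             if p in captured and not protocol.is_mandatory(p)]
    return CompletenessReport(
        captured=captured,
        missing_mandatory=missing,
        extra_non_mandatory=extra,
        processed=state.processed,
        skipped=state.skipped,
    )


def run_session(
    frames: Sequence[PhantomFrame],
    model,
    protocol: PlaneProtocol,
    threshold: float = 0.5,
    min_area: int = 0,
    keep_payload: bool = True,
) -> Tuple[CaptureState, CompletenessReport]:
    """Stream a whole video through the capture engine."""
    state = CaptureState()
    for frame in frames:
        ingest_frame(frame, model, state, protocol, threshold=threshold,
                     min_area=min_area, keep_payload=keep_payload)
    return state, finalize(state, protocol)
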