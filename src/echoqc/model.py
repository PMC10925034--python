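"""Multi-task encoder--decoder network: 28 structure segmentations plus an
image quality-score (QS) prediction from one grayscale frame.

Topology: a stem block maps the grayscale input to ``stem_channels``
feature maps at full resolution; five encoder stages each halve the
spatial resolution (so the input sides must be divisible by 32); five
decoder stages each upsample x2, concatenate the matching encoder output
(skip connection) and apply two convolution + batch-norm + LeakyReLU
layers; a final 1x1 convolution emits ``n_structures + 2`` channels --
one per structure, one background class, and one QS channel.

Structure and background channels are normalised per pixel with a softmax
so class scores are comparable; the QS scalar is the spatial mean of the
QS channel, shifted to the middle of the 1..10 scale and clamped.  Encoder
stage widths are configuration: a tiny desk-scale preset trains in minutes
on a CPU, while :data:`REGNETY_16GF_WIDTHS` mirrors the published
RegNetY-1.6GF stage widths for a topology-faithful variant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .nn import Adam, Conv2d, ConvBNAct, Param, UpsampleNearest2

#: Stage widths of the published RegNetY-1.6GF design, for the
#: topology-faithful preset (first entry repeats the narrow early stage).
REGNETY_16GF_WIDTHS: Tuple[int, ...] = (48, 48, 120, 336, 888)

#: Desk-scale default widths: trainable on one CPU in minutes.
TINY_WIDTHS: Tuple[int, ...] = (16, 32, 64, 96, 128)

#: Affine offset mapping a zero-mean QS channel onto the 1..10 scale.
QS_OFFSET = 5.5
QS_RANGE = (1.0, 10.0)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``encoder_widths`` / ``decoder_widths`` are the channel counts out of
    the five encoder / decoder stages; ``stem_channels`` is the width of
    the full-resolution stem block (16 by default); ``input_size`` must
    have both sides divisible by 32 (five halvings).
    """

    encoder_widths: Tuple[int, ...] = TINY_WIDTHS
    decoder_widths: Tuple[int, ...] = (96, 64, 48, 32, 24)
    stem_channels: int = 16
    n_structures: int = 28
    input_size: Tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        for name in ("encoder_widths", "decoder_widths"):
            widths = getattr(self, name)
            if len(widths) != 5:
                raise ValueError(f"{name} must have exactly 5 entries")
            if any(w < 1 for w in widths):
                raise ValueError(f"{name} entries must be >= 1")
        if self.stem_channels < 1 or self.n_structures < 1:
            raise ValueError("stem_channels and n_structures must be >= 1")
        h, w = self.input_size
        if h % 32 or w % 32 or h < 32 or w < 32:
            raise ValueError("input_size sides must be divisible by 32")

    @property
    def head_channels(self) -> int:
        """Output channels: structures + background + QS."""
        return self.n_structures + 2

    def to_dict(self) -> dict:
        return {
            "encoder_widths": list(self.encoder_widths),
            "decoder_widths": list(self.decoder_widths),
            "stem_channels": self.stem_channels,
            "n_structures": self.n_structures,
            "input_size": list(self.input_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(
            encoder_widths=tuple(d["encoder_widths"]),
            decoder_widths=tuple(d["decoder_widths"]),
            stem_channels=int(d["stem_channels"]),
            n_structures=int(d["n_structures"]),
            input_size=tuple(d["input_size"]),
        )


@dataclass
class SegmentationOutput:
    """Per-frame network output.

    ``structure_maps`` are per-structure probability maps (softmax over
    structures + background); ``qs_map`` is the raw QS channel and
    ``qs_pred`` its pooled, clamped scalar in [1, 10].
    """

    structure_maps: np.ndarray  # (S, H, W) in [0, 1]
    background_map: np.ndarray  # (H, W)
    qs_map: np.ndarray  # (H, W), unbounded
    qs_pred: float

    def __post_init__(self) -> None:
        if self.structure_maps.shape[1:] != self.background_map.shape:
            raise ValueError("map shapes disagree")
        if not QS_RANGE[0] <= self.qs_pred <= QS_RANGE[1]:
            raise ValueError("qs_pred outside [1, 10]")


class Network:
    """The encoder--decoder network.  Build via :func:`build_network`."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ew, dw = config.encoder_widths, config.decoder_widths

        self.stem = ConvBNAct(1, config.stem_channels, rng=rng)
        self.encoders = []
        prev = config.stem_channels
        for w in ew:
            self.encoders.append((ConvBNAct(prev, w, stride=2, rng=rng),
                                  ConvBNAct(w, w, rng=rng)))
            prev = w
        # decoder i consumes the previous feature map and the skip from
        # encoder stage 4-i (the stem for the last stage)
        skip_ch = [ew[3], ew[2], ew[1], ew[0], config.stem_channels]
        self.decoders = []
        for i, w in enumerate(dw):
            up = UpsampleNearest2()
            upconv = Conv2d(prev, w, kernel=3, rng=rng)
            block1 = ConvBNAct(w + skip_ch[i], w, rng=rng)
            block2 = ConvBNAct(w, w, rng=rng)
            self.decoders.append((up, upconv, block1, block2))
            prev = w
        self.head = Conv2d(prev, config.head_channels, kernel=1, rng=rng)

    # -- parameter plumbing ------------------------------------------------

    def params(self) -> List[Param]:
        ps = self.stem.params()
        for a, b in self.encoders:
            ps += a.params() + b.params()
        for up, upconv, b1, b2 in self.decoders:
            ps += upconv.params() + b1.params() + b2.params()
        return ps + self.head.params()

    def param_count(self) -> int:
        return sum(p.value.size for p in self.params())

    def checksum(self) -> float:
        """Deterministic scalar over all parameter values."""
        return float(sum(np.float64(p.value).sum() for p in self.params()))

    def state(self) -> List[np.ndarray]:
        arrays = [p.value.copy() for p in self.params()]
        for layer in self._bn_layers():
            arrays += [layer.running_mean.copy(), layer.running_var.copy()]
        return arrays

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrays[:len(ps)]):
            p.value[...] = a
        rest = arrays[len(ps):]
        for i, layer in enumerate(self._bn_layers()):
            layer.running_mean[...] = rest[2 * i]
            layer.running_var[...] = rest[2 * i + 1]

    def _bn_layers(self):
        layers = [self.stem.bn]
        for a, b in self.encoders:
            layers += [a.bn, b.bn]
        for up, upconv, b1, b2 in self.decoders:
            layers += [b1.bn, b2.bn]
        return layers

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (N, n_structures + 2, H, W) for a batch (N, 1, H, W)."""
        if x.ndim != 4 or x.shape[1] != 1 or \
                x.shape[2:] != tuple(self.config.input_size):
            raise ValueError(
                f"expected (N, 1, {self.config.input_size[0]}, "
                f"{self.config.input_size[1]}) input, got {x.shape}")
        s = self.stem.forward(x, train)
        skips = [s]
        h = s
        for a, b in self.encoders:
            h = b.forward(a.forward(h, train), train)
            skips.append(h)
        # decoder skip order: encoder stages 4..1 then the stem
        dec_skips = [skips[4], skips[3], skips[2], skips[1], skips[0]]
        self._split_ch = []
        for (up, upconv, b1, b2), skip in zip(self.decoders, dec_skips):
            h = upconv.forward(up.forward(h, train), train)
            self._split_ch.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h = b2.forward(b1.forward(h, train), train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients for the last forward pass."""
        dh = self.head.backward(dlogits)
        dskips = [None] * 5  # gradients flowing into dec_skips entries
        for i in range(4, -1, -1):
            up, upconv, b1, b2 = self.decoders[i]
            d = b1.backward(b2.backward(dh))
            ch = self._split_ch[i]
            d_up, d_skip = d[:, :ch], d[:, ch:]
            dskips[i] = d_skip
            dh = up.backward(upconv.backward(np.ascontiguousarray(d_up)))
        # dh is now the gradient at the bottom (encoder stage 5 output);
        # add each skip's gradient while walking the encoder backwards
        d = dh
        for i in range(4, -1, -1):
            a, b = self.encoders[i]
            d = a.backward(b.backward(d))
            d = d + dskips[4 - i]  # e3, e2, e1, e0, then the stem
        self.stem.backward(d)

    # -- inference ---------------------------------------------------------

    def predict_logits(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 2:
            raise ValueError("predict expects a single H x W image")
        return self.forward(image[None, None], train=False)[0]

    def predict(self, image: np.ndarray) -> SegmentationOutput:
        return output_from_logits(self.predict_logits(image),
                                  self.config.n_structures)


def softmax_channels(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def pooled_qs(qs_map: np.ndarray) -> float:
    """Spatial mean of the QS channel, affinely mapped and clamped."""
    return float(np.clip(qs_map.mean() + QS_OFFSET, *QS_RANGE))


def output_from_logits(logits: np.ndarray,
                       n_structures: int) -> SegmentationOutput:
    """Convert head logits (S + 2, H, W) into a :class:`SegmentationOutput`."""
    if logits.shape[0] != n_structures + 2:
        raise ValueError("channel count does not match n_structures + 2")
    probs = softmax_channels(logits[:n_structures + 1])
    return SegmentationOutput(
        structure_maps=probs[:n_structures],
        background_map=probs[n_structures],
        qs_map=logits[n_structures + 1],
        qs_pred=pooled_qs(logits[n_structures + 1]),
    )


def build_network(config: NetworkConfig, seed: int = 0) -> Network:
    """Construct a seeded network; same (config, seed) -> same parameters."""
    return Network(config, seed=seed)


def binarize(output: SegmentationOutput, threshold: float = 0.5,
             min_area: int = 0) -> Dict[str, np.ndarray]:
    """Threshold probability maps into binary masks and presence flags.

    Returns ``{"masks": (S, H, W) bool, "present": (S,) bool}``; a
    structure is predicted present iff its mask area exceeds ``min_area``
    pixels.
    """

    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    masks = output.structure_maps > threshold
    present = masks.sum(axis=(1, 2)) > min_area
    return {"masks": masks, "present": present}


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(network: Network, path) -> None:
    """Save parameters as .npz with a JSON config sidecar."""
    arrays = {f"a{i}": a for i, a in enumerate(network.state())}
    np.savez(path, **arrays)
    sidecar = str(path) + ".json" if not str(path).endswith(".npz") \
        else str(path)[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump(network.config.to_dict(), fh, indent=2)


def load_checkpoint(path) -> Network:
    sidecar = str(path) + ".json" if not str(path).endswith(".npz") \
        else str(path)[:-4] + ".json"
    with open(sidecar) as fh:
        config = NetworkConfig.from_dict(json.load(fh))
    network = Network(config, seed=0)
    with np.load(str(path)) as data:
        arrays = [data[f"a{i}"] for i in range(len(data.files))]
    network.load_state(arrays)
    return network
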