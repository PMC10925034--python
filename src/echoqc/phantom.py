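"""Synthetic fetal-echo phantom: frames, masks, quality scores, videos.

Real screening data cannot ship with the toolkit, so this module generates
ultrasound-like grayscale frames with known ground truth.  Each standard
plane is a fixed layout of parametric primitives (ellipse / annulus /
ribbon) standing in for its anatomical features; a seeded jitter varies the
geometry between frames.  Degradations -- acoustic shadow, blur, gain bias
and multiplicative speckle -- are applied to the rendered image only: the
ground-truth masks are always the clean rasterised primitives, so the image
quality score (QS) measures how well the *image* shows structures that are
known to be there.

The QS is an integer on the 1..10 scale used in screening quality
assessment: 10 for a perfectly outlined structure, 5 for a structure seen
through a degree of shadow or blurriness, 1 when the outline cannot be seen
at all.  :func:`qs_from_degradation` maps the physical degradation knobs
onto that scale through those three anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import polygon as _draw_polygon

from .planes import ALL_PLANES, DEFAULT_FEATURES, NONHEART, STANDARD_PLANES

# --------------------------------------------------------------------------
# Geometry primitives
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Primitive:
    """Parametric shape in fractional image coordinates.

    ``center`` is (row, col) in [0, 1]^2; ``axes`` are (semi-minor along
    rows, semi-major along cols) as fractions of the image side;
    ``rotation`` is radians, counter-clockwise.  ``kind`` selects the
    rasteriser: a filled ellipse, an annulus (elliptical ring with relative
    ``thickness``), or a ribbon (rotated rectangle of ``axes`` = (length/2,
    width/2)).
    """

    kind: str  # "ellipse" | "annulus" | "ribbon"
    center: Tuple[float, float]
    axes: Tuple[float, float]
    rotation: float = 0.0
    thickness: float = 0.4  # annulus only: ring thickness relative to axes

    def __post_init__(self) -> None:
        if self.kind not in ("ellipse", "annulus", "ribbon"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if not (0.0 < self.center[0] < 1.0 and 0.0 < self.center[1] < 1.0):
            raise ValueError("primitive center must lie inside the frame")
        if self.axes[0] <= 0 or self.axes[1] <= 0:
            raise ValueError("primitive axes must be strictly positive")
        if self.kind == "annulus" and not 0.0 < self.thickness < 1.0:
            raise ValueError("annulus thickness must be in (0, 1)")

    def rasterize(self, size: Tuple[int, int]) -> np.ndarray:
        """Binary mask of the primitive on an H x W grid."""
        h, w = size
        s = min(h, w)
        r0, c0 = self.center[0] * h, self.center[1] * w
        a, b = self.axes[0] * s, self.axes[1] * s
        mask = np.zeros((h, w), dtype=bool)
        if self.kind in ("ellipse", "annulus"):
            rr, cc = _draw_ellipse(r0, c0, a, b, shape=(h, w),
                                   rotation=self.rotation)
            mask[rr, cc] = True
            if self.kind == "annulus":
                inner = np.zeros_like(mask)
                ai = a * (1.0 - self.thickness)
                bi = b * (1.0 - self.thickness)
                if ai > 0.5 and bi > 0.5:
                    rr, cc = _draw_ellipse(r0, c0, ai, bi, shape=(h, w),
                                           rotation=self.rotation)
                    inner[rr, cc] = True
                mask &= ~inner
        else:  # ribbon: rotated rectangle, axes = (half-length, half-width)
            hl, hw = a, b
            ca, sa = math.cos(self.rotation), math.sin(self.rotation)
            # corners in (row, col) offsets
            corners = np.array([
                (-hw * ca - hl * sa, hl * ca - hw * sa),
                (-hw * ca + hl * sa, -hl * ca - hw * sa),
                (hw * ca + hl * sa, -hl * ca + hw * sa),
                (hw * ca - hl * sa, hl * ca + hw * sa),
            ])
            rr, cc = _draw_polygon(r0 + corners[:, 0], c0 + corners[:, 1],
                                   shape=(h, w))
            mask[rr, cc] = True
        return mask


@dataclass(frozen=True)
class StructureSpec:
    """One anatomical feature: a named primitive with an echo intensity."""

    name: str
    shape: Primitive
    base_intensity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_intensity <= 1.0:
            raise ValueError("base_intensity must be in [0, 1]")


@dataclass(frozen=True)
class PlaneSpec:
    """A standard plane: its structures and minimum required feature names."""

    plane: str
    structures: Tuple[StructureSpec, ...] = ()
    required: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.plane not in ALL_PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        names = [s.name for s in self.structures]
        if len(set(names)) != len(names):
            raise ValueError("structure names must be unique within a plane")
        if not set(self.required) <= set(names):
            raise ValueError("required must be a subset of structure names")
        if self.plane == NONHEART and self.structures:
            raise ValueError("NonHeart planes have no structures")

    @property
    def structure_names(self) -> Tuple[str, ...]:
        return tuple(s.name for s in self.structures)


# --------------------------------------------------------------------------
# Degradation and quality score
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DegradationConfig:
    """Physical image-degradation knobs.

    shadow_fraction: fraction in [0, 1] of the insonation fan occluded by a
        dark acoustic-shadow wedge from the transducer apex.
    blur_sigma: Gaussian blur radius in pixels (>= 0).
    gain_offset: additive intensity bias in [-0.5, 0.5] (mis-set gain).
    speckle_level: variance of multiplicative speckle noise (>= 0).
    """

    shadow_fraction: float = 0.0
    blur_sigma: float = 0.0
    gain_offset: float = 0.0
    speckle_level: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shadow_fraction <= 1.0:
            raise ValueError("shadow_fraction must be in [0, 1]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not -0.5 <= self.gain_offset <= 0.5:
            raise ValueError("gain_offset must be in [-0.5, 0.5]")
        if self.speckle_level < 0:
            raise ValueError("speckle_level must be >= 0")


#: Calibrated preset realising the mid-scale QS anchor ("a degree of shadow
#: or blurriness" -> QS 5).
MODERATE_DEGRADATION = DegradationConfig(shadow_fraction=0.4, blur_sigma=2.0)

# Weighted degradation index: shadow alone saturates the scale; the blur
# coefficient is calibrated so the moderate preset lands exactly on QS 5.
_BLUR_COEF = (5.0 / 9.0 - 0.4) / 2.0  # = 7/90 per pixel of sigma
_GAIN_COEF = 0.6
_SPECKLE_COEF = 0.4


def qs_from_degradation(degradation: DegradationConfig) -> int:
    """Map degradation to the integer 1..10 quality score.

    Piecewise-linear in a weighted degradation index, anchored at three
    points of the scale: no degradation -> 10, the moderate shadow/blur
    preset -> 5, full occlusion -> 1.  Monotone non-increasing in every
    degradation field.
    """

    d = degradation
    index = (
        d.shadow_fraction
        + _BLUR_COEF * d.blur_sigma
        + _GAIN_COEF * abs(d.gain_offset)
        + _SPECKLE_COEF * min(d.speckle_level, 1.0)
    )
    index = min(index, 1.0)
    # round-half-up so the mid anchor (index 5/9 -> 5.5) lands on 5
    return int(np.clip(math.floor(10.0 - 9.0 * index + 0.5), 1, 10))


# --------------------------------------------------------------------------
# Frames
# --------------------------------------------------------------------------


@dataclass
class PhantomFrame:
    """One synthetic frame with its ground truth."""

    image: np.ndarray  # H x W float in [0, 1]
    masks: Dict[str, np.ndarray]  # per-structure H x W bool
    qs_true: int
    plane: str
    frame_index: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.qs_true <= 10:
            raise ValueError("qs_true must be in 1..10")
        for name, m in self.masks.items():
            if m.shape != self.image.shape:
                raise ValueError(f"mask {name!r} shape mismatch")


def _jitter(primitive: Primitive, rng: np.random.Generator) -> Primitive:
    """Seeded geometric variation: shift, rotate, scale.

    Large enough that a structure's exact extent cannot be recovered from
    its canonical plane position alone -- an occluded structure is
    genuinely lost, which is what ties the quality score to achievable
    segmentation accuracy.
    """
    dr, dc = rng.uniform(-0.03, 0.03, size=2)
    drot = rng.uniform(-0.15, 0.15)
    scale = rng.uniform(0.88, 1.12)
    center = (float(np.clip(primitive.center[0] + dr, 0.05, 0.95)),
              float(np.clip(primitive.center[1] + dc, 0.05, 0.95)))
    return replace(
        primitive,
        center=center,
        axes=(primitive.axes[0] * scale, primitive.axes[1] * scale),
        rotation=primitive.rotation + drot,
    )


def _shadow_mask(size: Tuple[int, int], fraction: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Wedge of occluded pixels fanning out from the transducer apex."""
    h, w = size
    apex_r, apex_c = -0.05 * h, 0.5 * w
    rows, cols = np.mgrid[0:h, 0:w]
    ang = np.arctan2(cols - apex_c, rows - apex_r)  # 0 = straight down
    fan = math.radians(75.0)  # half-angle of the insonation fan
    half = fraction * fan
    max_off = max(fan - half, 0.0)
    center = rng.uniform(-max_off, max_off)
    return np.abs(ang - center) <= half


def generate_frame(
    plane_spec: PlaneSpec,
    degradation: DegradationConfig,
    seed: int,
    size: Tuple[int, int] = (128, 128),
    frame_index: int = 0,
) -> PhantomFrame:
    """Render one frame of a plane under the given degradation.

    Masks are the clean rasterised (jittered) primitives -- degradation
    never touches the ground truth.  Deterministic for a fixed seed.
    """

    h, w = int(size[0]), int(size[1])
    if h < 32 or w < 32:
        raise ValueError("frame size must be at least 32 x 32")
    rng = np.random.default_rng(seed)

    # seeded geometry first, so masks do not depend on degradation draws
    jittered = [
        StructureSpec(s.name, _jitter(s.shape, rng), s.base_intensity)
        for s in plane_spec.structures
    ]
    masks = {s.name: s.shape.rasterize((h, w)) for s in jittered}

    # background: dim smoothed speckle texture
    image = 0.12 + 0.05 * gaussian_filter(rng.standard_normal((h, w)), 1.5)

    if plane_spec.plane != NONHEART:
        # thoracic context: a dim rib-cage rim surrounds the heart on every
        # cardiac plane.  It is rendering context only (never annotated),
        # but gives frames of cardiac planes a global appearance cue that
        # non-heart frames lack.
        rim = Primitive(
            kind="annulus",
            center=(float(np.clip(0.5 + rng.uniform(-0.03, 0.03), 0.05,
                                  0.95)),
                    float(np.clip(0.5 + rng.uniform(-0.03, 0.03), 0.05,
                                  0.95))),
            axes=(0.42, 0.46), rotation=rng.uniform(-0.1, 0.1),
            thickness=0.12,
        )
        image[rim.rasterize((h, w))] = 0.35

    for s in jittered:
        image[masks[s.name]] = s.base_intensity

    if plane_spec.plane == NONHEART:
        # non-anatomical clutter: structure-like blobs with no annotation
        for _ in range(rng.integers(2, 5)):
            blob = Primitive(
                kind="ellipse",
                center=(rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8)),
                axes=(rng.uniform(0.04, 0.12), rng.uniform(0.04, 0.12)),
                rotation=rng.uniform(0, math.pi),
            )
            image[blob.rasterize((h, w))] = rng.uniform(0.35, 0.9)

    # degradation chain: blur, speckle, gain, shadow
    d = degradation
    if d.blur_sigma > 0:
        image = gaussian_filter(image, d.blur_sigma)
    if d.speckle_level > 0:
        image = image * (1.0 + math.sqrt(d.speckle_level)
                         * rng.standard_normal((h, w)))
    image = image + d.gain_offset
    if d.shadow_fraction > 0:
        # inside the wedge the echo is lost, not merely dimmed: residual
        # contrast drops ~16x and in-wedge noise breaks edge continuity,
        # so an occluded structure cannot be recovered from the image
        wedge = _shadow_mask((h, w), d.shadow_fraction, rng)
        occluded = (image * 0.06 + 0.06
                    + 0.03 * rng.standard_normal((h, w)))
        image = np.where(wedge, occluded, image)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    return PhantomFrame(
        image=image,
        masks=masks,
        qs_true=qs_from_degradation(degradation),
        plane=plane_spec.plane,
        frame_index=frame_index,
    )


# --------------------------------------------------------------------------
# Default plane layouts (the 28-feature registry, rendered)
# --------------------------------------------------------------------------

_E, _A, _R = "ellipse", "annulus", "ribbon"

# name -> (kind, center, axes, rotation, intensity)
_LAYOUTS: Dict[str, List[Tuple[str, str, Tuple[float, float],
                               Tuple[float, float], float, float]]] = {
    "Situs": [
        ("stomach", _E, (0.55, 0.38), (0.10, 0.13), 0.3, 0.30),
        ("situs_desc_aorta", _E, (0.62, 0.60), (0.055, 0.055), 0.0, 0.60),
        ("situs_spine", _E, (0.80, 0.50), (0.06, 0.08), 0.0, 0.92),
    ],
    "4CV": [
        ("left_ventricle", _E, (0.42, 0.36), (0.13, 0.09), 0.4, 0.28),
        ("right_ventricle", _E, (0.37, 0.61), (0.12, 0.09), -0.3, 0.45),
        ("left_atrium", _E, (0.65, 0.39), (0.09, 0.08), 0.0, 0.62),
        ("right_atrium", _E, (0.64, 0.63), (0.09, 0.08), 0.0, 0.78),
        ("septal_crux", _E, (0.52, 0.50), (0.05, 0.05), 0.0, 0.95),
    ],
    "VSV": [
        ("ventricular_septum", _R, (0.50, 0.50), (0.22, 0.036), 1.0, 0.92),
        ("vsv_lv_wall", _R, (0.33, 0.42), (0.20, 0.034), 0.8, 0.62),
        ("vsv_rv_wall", _R, (0.67, 0.58), (0.20, 0.034), 0.8, 0.76),
    ],
    "RVOT": [
        ("rvot_pulmonary_artery", _R, (0.44, 0.57), (0.17, 0.045), -0.5, 0.55),
        ("rvot_infundibulum", _E, (0.58, 0.33), (0.09, 0.08), 0.0, 0.30),
        ("pulmonary_valve", _E, (0.47, 0.44), (0.05, 0.05), 0.0, 0.90),
    ],
    "LVOT": [
        ("lvot_aortic_root", _R, (0.45, 0.58), (0.17, 0.045), 0.6, 0.60),
        ("lvot_outflow", _E, (0.62, 0.37), (0.10, 0.08), 0.2, 0.30),
        ("aortic_valve", _E, (0.51, 0.49), (0.05, 0.05), 0.0, 0.90),
    ],
    "3VV": [
        ("threevv_pulmonary_trunk", _E, (0.44, 0.30), (0.08, 0.06), 0.4, 0.50),
        ("threevv_asc_aorta", _E, (0.47, 0.51), (0.06, 0.05), 0.0, 0.65),
        ("threevv_svc", _E, (0.50, 0.68), (0.055, 0.05), 0.0, 0.80),
        ("threevv_spine", _E, (0.80, 0.55), (0.055, 0.065), 0.0, 0.95),
    ],
    "3VT": [
        ("threevt_ductal_arch", _R, (0.44, 0.40), (0.19, 0.04), -0.35, 0.55),
        ("threevt_aortic_arch", _R, (0.54, 0.57), (0.16, 0.045), -0.5, 0.68),
        ("threevt_svc", _E, (0.40, 0.74), (0.055, 0.05), 0.0, 0.82),
        ("trachea", _A, (0.62, 0.76), (0.05, 0.05), 0.0, 0.95),
    ],
    "Arch": [
        ("aortic_arch", _A, (0.50, 0.48), (0.20, 0.24), 0.1, 0.62),
        ("head_neck_vessels", _R, (0.24, 0.52), (0.12, 0.032), 1.45, 0.80),
        ("arch_desc_aorta", _R, (0.72, 0.68), (0.16, 0.045), 0.3, 0.48),
    ],
}

# annulus entries need a thickness; ribbons interpret axes as half-sizes
_ANNULUS_THICKNESS = {"trachea": 0.45, "aortic_arch": 0.28}


def default_plane_specs() -> Dict[str, PlaneSpec]:
    """Shipped layouts for the eight standard planes plus NonHeart.

    Feature names and counts follow the default 28-feature registry in
    :mod:`echoqc.planes`; geometry and intensities are the phantom's own
    rendering choices.
    """

    specs: Dict[str, PlaneSpec] = {}
    for plane in STANDARD_PLANES:
        structures = []
        for name, kind, center, axes, rot, intensity in _LAYOUTS[plane]:
            prim = Primitive(
                kind=kind, center=center, axes=axes, rotation=rot,
                thickness=_ANNULUS_THICKNESS.get(name, 0.4),
            )
            structures.append(StructureSpec(name, prim, intensity))
        assert tuple(s.name for s in structures) == DEFAULT_FEATURES[plane]
        specs[plane] = PlaneSpec(
            plane=plane,
            structures=tuple(structures),
            required=DEFAULT_FEATURES[plane],
        )
    specs[NONHEART] = PlaneSpec(plane=NONHEART)
    return specs


# --------------------------------------------------------------------------
# Videos
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """A run of consecutive frames of one plane.

    ``degradations`` is either a single config applied to every frame or a
    schedule with one config per frame.
    """

    plane_spec: PlaneSpec
    degradations: Union[DegradationConfig, Tuple[DegradationConfig, ...]]
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("segment needs at least one frame")
        if isinstance(self.degradations, tuple) and \
                len(self.degradations) != self.n_frames:
            raise ValueError("degradation schedule length != n_frames")

    def degradation_at(self, i: int) -> DegradationConfig:
        if isinstance(self.degradations, tuple):
            return self.degradations[i]
        return self.degradations


@dataclass(frozen=True)
class VideoScript:
    """Ordered segments emulating a screening sweep through planes."""

    segments: Tuple[Segment, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("script needs at least one segment")

    @property
    def n_frames(self) -> int:
        return sum(seg.n_frames for seg in self.segments)


def _frame_seed(script_seed: int, frame_index: int) -> int:
    ss = np.random.SeedSequence(entropy=script_seed,
                                spawn_key=(frame_index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_video(
    script: VideoScript,
    size: Tuple[int, int] = (128, 128),
) -> List[PhantomFrame]:
    """Materialise a script into an ordered frame sequence.

    Frame indices are consecutive across segments; every frame's seed is
    derived from the script seed and its index, so the whole video is
    reproducible frame-by-frame.
    """

    frames: List[PhantomFrame] = []
    idx = 0
    for seg in script.segments:
        for i in range(seg.n_frames):
            frames.append(generate_frame(
                seg.plane_spec,
                seg.degradation_at(i),
                seed=_frame_seed(script.seed, idx),
                size=size,
                frame_index=idx,
            ))
            idx += 1
    return frames


def degradation_sweep(n: int, max_shadow: float = 1.0,
                      max_blur: float = 3.0) -> Tuple[DegradationConfig, ...]:
    """Schedule sweeping linearly from clean to heavily degraded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ts = np.linspace(0.0, 1.0, n)
    return tuple(
        DegradationConfig(shadow_fraction=float(t * max_shadow),
                          blur_sigma=float(t * max_blur))
        for t in ts
    )


def random_degradation(rng: np.random.Generator,
                       max_shadow: float = 0.9) -> DegradationConfig:
    """One random degradation draw covering the QS range."""
    return DegradationConfig(
        shadow_fraction=float(rng.uniform(0.0, max_shadow)),
        blur_sigma=float(rng.uniform(0.0, 3.0)),
        gain_offset=float(rng.uniform(-0.2, 0.2)),
        speckle_level=float(rng.uniform(0.0, 0.3)),
    )


def random_script(
    rng: np.random.Generator,
    plane_specs: Optional[Dict[str, PlaneSpec]] = None,
    n_segments: Tuple[int, int] = (2, 6),
    frames_per_segment: Tuple[int, int] = (3, 10),
    nonheart_prob: float = 0.25,
) -> VideoScript:
    """Random screening-sweep script with per-frame degradation draws."""
    specs = plane_specs or default_plane_specs()
    segs = []
    for _ in range(int(rng.integers(n_segments[0], n_segments[1] + 1))):
        plane = (NONHEART if rng.uniform() < nonheart_prob
                 else str(rng.choice(STANDARD_PLANES)))
        n = int(rng.integers(frames_per_segment[0],
                             frames_per_segment[1] + 1))
        sched = tuple(random_degradation(rng) for _ in range(n))
        segs.append(Segment(specs[plane], sched, n))
    return VideoScript(segments=tuple(segs),
                       seed=int(rng.integers(0, 2 ** 31)))
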