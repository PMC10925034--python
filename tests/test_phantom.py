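"""Phantom generator: determinism, ground-truth consistency, QS anchors."""

import numpy as np
import pytest

from echoqc.phantom import (MODERATE_DEGRADATION, DegradationConfig,
                            PhantomFrame, PlaneSpec, Primitive, Segment,
                            StructureSpec, VideoScript, default_plane_specs,
                            degradation_sweep, generate_frame, generate_video,
                            qs_from_degradation, random_script)
from echoqc.planes import NONHEART, STANDARD_PLANES


class TestQualityScore:
    def test_verbal_anchors(self):
        """10 = perfect outline, 5 = moderate shadow/blur, 1 = not seen."""
        assert qs_from_degradation(DegradationConfig()) == 10
        assert qs_from_degradation(MODERATE_DEGRADATION) == 5
        assert qs_from_degradation(
            DegradationConfig(shadow_fraction=1.0)) == 1

    def test_full_shadow_dominates(self):
        deg = DegradationConfig(shadow_fraction=1.0, blur_sigma=3.0,
                                gain_offset=0.4, speckle_level=1.0)
        assert qs_from_degradation(deg) == 1

    @pytest.mark.parametrize("field", ["shadow_fraction", "blur_sigma",
                                       "gain_offset", "speckle_level"])
    def test_monotone_in_each_field(self, field):
        rng = np.random.default_rng(7)
        hi = {"shadow_fraction": 1.0, "blur_sigma": 4.0,
              "gain_offset": 0.5, "speckle_level": 1.5}[field]
        for _ in range(50):
            base = dict(
                shadow_fraction=rng.uniform(0, 0.5),
                blur_sigma=rng.uniform(0, 2),
                gain_offset=rng.uniform(0, 0.3),
                speckle_level=rng.uniform(0, 0.5),
            )
            lo_val, hi_val = sorted(rng.uniform(0, hi, size=2))
            lo = qs_from_degradation(
                DegradationConfig(**{**base, field: lo_val}))
            hi_qs = qs_from_degradation(
                DegradationConfig(**{**base, field: hi_val}))
            assert hi_qs <= lo

    def test_sweep_covers_full_scale(self):
        scores = {qs_from_degradation(d) for d in degradation_sweep(200)}
        assert scores == set(range(1, 11))

    @pytest.mark.parametrize("kwargs", [
        {"shadow_fraction": -0.1}, {"shadow_fraction": 1.2},
        {"blur_sigma": -1}, {"gain_offset": 0.7}, {"speckle_level": -0.1},
    ])
    def test_out_of_range_degradation_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DegradationConfig(**kwargs)


class TestGenerateFrame:
    def test_clean_frame_has_top_qs_and_all_masks(self, plane_specs, clean):
        frame = generate_frame(plane_specs["4CV"], clean, seed=0,
                               size=(64, 64))
        assert frame.qs_true == 10
        assert set(frame.masks) == set(plane_specs["4CV"].structure_names)
        assert all(m.any() for m in frame.masks.values())

    def test_nonheart_frames_have_no_masks(self, plane_specs):
        frame = generate_frame(plane_specs[NONHEART],
                               DegradationConfig(blur_sigma=1.0), seed=1,
                               size=(64, 64))
        assert frame.masks == {}

    def test_deterministic_for_fixed_seed(self, plane_specs):
        deg = DegradationConfig(shadow_fraction=0.3, speckle_level=0.2)
        a = generate_frame(plane_specs["3VT"], deg, seed=42, size=(64, 64))
        b = generate_frame(plane_specs["3VT"], deg, seed=42, size=(64, 64))
        assert np.array_equal(a.image, b.image)
        for name in a.masks:
            assert np.array_equal(a.masks[name], b.masks[name])

    def test_masks_independent_of_degradation(self, plane_specs, clean):
        heavy = DegradationConfig(shadow_fraction=0.9, blur_sigma=3.0,
                                  speckle_level=0.8)
        a = generate_frame(plane_specs["Situs"], clean, seed=5,
                           size=(64, 64))
        b = generate_frame(plane_specs["Situs"], heavy, seed=5,
                           size=(64, 64))
        for name in a.masks:
            assert np.array_equal(a.masks[name], b.masks[name])
        assert not np.array_equal(a.image, b.image)

    def test_image_range_and_dtype(self, plane_specs):
        deg = DegradationConfig(gain_offset=-0.4, speckle_level=1.0)
        frame = generate_frame(plane_specs["LVOT"], deg, seed=3,
                               size=(64, 64))
        assert frame.image.min() >= 0.0 and frame.image.max() <= 1.0

    def test_too_small_frame_rejected(self, plane_specs, clean):
        with pytest.raises(ValueError):
            generate_frame(plane_specs["4CV"], clean, seed=0, size=(16, 16))


class TestPrimitivesAndSpecs:
    def test_all_planes_have_layouts(self, plane_specs):
        assert set(plane_specs) == set(STANDARD_PLANES) | {NONHEART}
        n_structures = sum(len(plane_specs[p].structures)
                           for p in STANDARD_PLANES)
        assert n_structures == 28

    @pytest.mark.parametrize("kwargs", [
        {"kind": "blob", "center": (0.5, 0.5), "axes": (0.1, 0.1)},
        {"kind": "ellipse", "center": (1.5, 0.5), "axes": (0.1, 0.1)},
        {"kind": "ellipse", "center": (0.5, 0.5), "axes": (0.0, 0.1)},
        {"kind": "annulus", "center": (0.5, 0.5), "axes": (0.1, 0.1),
         "thickness": 1.5},
    ])
    def test_invalid_primitive_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Primitive(**kwargs)

    def test_duplicate_structure_names_rejected(self):
        prim = Primitive(kind="ellipse", center=(0.5, 0.5), axes=(0.1, 0.1))
        s = StructureSpec("x", prim, 0.5)
        with pytest.raises(ValueError):
            PlaneSpec(plane="4CV", structures=(s, s), required=("x",))

    def test_required_must_be_subset(self):
        prim = Primitive(kind="ellipse", center=(0.5, 0.5), axes=(0.1, 0.1))
        s = StructureSpec("x", prim, 0.5)
        with pytest.raises(ValueError):
            PlaneSpec(plane="4CV", structures=(s,), required=("y",))

    def test_rasterized_area_positive(self):
        for kind in ("ellipse", "annulus", "ribbon"):
            prim = Primitive(kind=kind, center=(0.5, 0.5), axes=(0.2, 0.15),
                             rotation=0.3)
            assert prim.rasterize((64, 64)).sum() > 0


class TestGenerateVideo:
    def test_single_segment(self, plane_specs, clean):
        script = VideoScript(
            segments=(Segment(plane_specs["4CV"], clean, 10),), seed=0)
        frames = generate_video(script, size=(64, 64))
        assert len(frames) == 10
        assert all(f.plane == "4CV" for f in frames)
        assert [f.frame_index for f in frames] == list(range(10))

    def test_alternating_nonheart_segments(self, plane_specs, clean):
        script = VideoScript(segments=(
            Segment(plane_specs[NONHEART], clean, 3),
            Segment(plane_specs["4CV"], clean, 3),
            Segment(plane_specs[NONHEART], clean, 3),
        ), seed=1)
        frames = generate_video(script, size=(64, 64))
        assert len(frames) == 9
        for f in frames:
            if f.plane == NONHEART:
                assert f.masks == {}

    def test_qs_peak_at_scheduled_frame(self, plane_specs):
        """A schedule whose degradation dips at frame 7 peaks the QS there."""
        sched = tuple(
            DegradationConfig(shadow_fraction=0.0 if i == 7 else 0.6)
            for i in range(12))
        script = VideoScript(
            segments=(Segment(plane_specs["VSV"], sched, 12),), seed=2)
        frames = generate_video(script, size=(64, 64))
        qs = [f.qs_true for f in frames]
        assert int(np.argmax(qs)) == 7
        assert qs[7] == max(qs)

    def test_video_determinism(self, plane_specs):
        rng = np.random.default_rng(3)
        script = random_script(rng, plane_specs)
        a = generate_video(script, size=(64, 64))
        b = generate_video(script, size=(64, 64))
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.image, fb.image)

    def test_empty_script_rejected(self):
        with pytest.raises(ValueError):
            VideoScript(segments=(), seed=0)

    def test_schedule_length_mismatch_rejected(self, plane_specs, clean):
        with pytest.raises(ValueError):
            Segment(plane_specs["4CV"], (clean,), 2)
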