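"""Auto-capture engine: plane assignment, best-frame retention, reports."""

import numpy as np
import pytest

from echoqc.autocapture import (CaptureState, OracleModel, assign_plane,
                                finalize, ingest_frame, run_session)
from echoqc.metrics import dice
from echoqc.model import SegmentationOutput
from echoqc.phantom import (DegradationConfig, Segment, VideoScript,
                            generate_video, random_script)
from echoqc.planes import NONHEART, STANDARD_PLANES


@pytest.fixture(scope="module")
def names(protocol):
    return protocol.feature_names


def synthetic_output(names, areas, qs_pred=5.0, size=16):
    """Fabricated network output with given per-structure mask areas."""
    maps = np.zeros((len(names), size, size), np.float32)
    for name, area in areas.items():
        i = names.index(name)
        flat = maps[i].reshape(-1)
        flat[:area] = 0.9
    return SegmentationOutput(
        structure_maps=maps,
        background_map=1.0 - maps.max(axis=0),
        qs_map=np.full((size, size), qs_pred - 5.5, np.float32),
        qs_pred=qs_pred)


class TestAssignPlane:
    def test_complete_plane_is_assigned(self, protocol, names):
        areas = {n: 10 for n in protocol.required("4CV")}
        out = synthetic_output(list(names), areas)
        assert assign_plane(out, protocol, names) == "4CV"

    def test_empty_output_is_nonheart(self, protocol, names):
        out = synthetic_output(list(names), {})
        assert assign_plane(out, protocol, names) == NONHEART

    def test_incomplete_required_set_is_nonheart(self, protocol, names):
        req = protocol.required("Situs")
        areas = {n: 10 for n in req[:-1]}  # one feature missing
        out = synthetic_output(list(names), areas)
        assert assign_plane(out, protocol, names) == NONHEART

    def test_double_attainment_prefers_larger_presence(self, protocol,
                                                       names):
        areas = {n: 4 for n in protocol.required("3VT")}
        areas.update({n: 40 for n in protocol.required("3VV")})
        out = synthetic_output(list(names), areas)
        assert assign_plane(out, protocol, names) == "3VV"
        # and the reverse
        areas = {n: 40 for n in protocol.required("3VT")}
        areas.update({n: 4 for n in protocol.required("3VV")})
        out = synthetic_output(list(names), areas)
        assert assign_plane(out, protocol, names) == "3VT"

    def test_exact_tie_falls_back_to_plane_order(self, protocol, names):
        areas = {n: 10 for n in protocol.required("3VV")}
        areas.update({n: 10 for n in protocol.required("3VT")})
        out = synthetic_output(list(names), areas)
        winner = assign_plane(out, protocol, names)
        first = next(p for p in STANDARD_PLANES if p in ("3VV", "3VT"))
        assert winner == first

    def test_min_area_gate(self, protocol, names):
        areas = {n: 1 for n in protocol.required("Situs")}
        out = synthetic_output(list(names), areas)
        assert assign_plane(out, protocol, names, min_area=2) == NONHEART


class TestCaptureSession:
    def _script(self, plane_specs, plane, shadows, seed=0):
        sched = tuple(DegradationConfig(shadow_fraction=s) for s in shadows)
        return VideoScript(
            segments=(Segment(plane_specs[plane], sched, len(shadows)),),
            seed=seed)

    def test_peak_qs_frame_is_captured(self, plane_specs, protocol, names):
        shadows = [0.6, 0.5, 0.4, 0.6, 0.7, 0.5, 0.6, 0.0, 0.5, 0.6]
        frames = generate_video(self._script(plane_specs, "4CV", shadows),
                                size=(64, 64))
        model = OracleModel(names)
        state, report = run_session(frames, model, protocol)
        assert state.best["4CV"].frame_index == 7
        assert state.best["4CV"].qs_pred == 10.0

    def test_tie_keeps_earlier_frame(self, plane_specs, protocol, names):
        shadows = [0.3, 0.3, 0.3]  # identical QS throughout
        frames = generate_video(self._script(plane_specs, "VSV", shadows),
                                size=(64, 64))
        state, _ = run_session(frames, OracleModel(names), protocol)
        assert state.best["VSV"].frame_index == 0

    def test_nonheart_video_captures_nothing(self, plane_specs, protocol,
                                             names):
        frames = generate_video(self._script(plane_specs, NONHEART,
                                             [0.0, 0.1, 0.2]),
                                size=(64, 64))
        state, report = run_session(frames, OracleModel(names), protocol)
        assert state.best == {}
        assert set(report.missing_mandatory) == \
            set(protocol.mandatory_planes)

    def test_online_max_equals_exhaustive_max(self, plane_specs, protocol,
                                              names):
        """Across random scripts, each captured QS equals the script max."""
        rng = np.random.default_rng(9)
        model = OracleModel(names)
        for _ in range(5):
            script = random_script(rng, plane_specs)
            frames = generate_video(script, size=(64, 64))
            state, _ = run_session(frames, model, protocol)
            best_true = {}
            for f in frames:
                if f.plane != NONHEART:
                    best_true[f.plane] = max(best_true.get(f.plane, 0),
                                             f.qs_true)
            assert {p: bf.qs_pred for p, bf in state.best.items()} == \
                {p: float(q) for p, q in best_true.items()}

    def test_order_invariance_of_max_value(self, plane_specs, protocol,
                                           names):
        shadows = [0.5, 0.0, 0.7]
        fwd = generate_video(self._script(plane_specs, "Arch", shadows),
                             size=(64, 64))
        rev = generate_video(
            self._script(plane_specs, "Arch", shadows[::-1]), size=(64, 64))
        s_fwd, _ = run_session(fwd, OracleModel(names), protocol)
        s_rev, _ = run_session(rev, OracleModel(names), protocol)
        assert s_fwd.best["Arch"].qs_pred == s_rev.best["Arch"].qs_pred

    def test_corrupt_frame_is_skipped_not_fatal(self, plane_specs, protocol,
                                                names):
        frames = generate_video(
            self._script(plane_specs, "LVOT", [0.0, 0.1]), size=(64, 64))

        class ExplodingModel(OracleModel):
            def predict(self, frame):
                if frame.frame_index == 0:
                    raise RuntimeError("corrupt frame")
                return super().predict(frame)

        state, report = run_session(frames, ExplodingModel(names), protocol)
        assert state.skipped == 1
        assert state.processed == 1
        assert len(state.skip_log) == 1
        assert "LVOT" in state.best


class TestCompletenessReport:
    def test_missing_plane_listed(self, plane_specs, protocol, names):
        script = VideoScript(segments=tuple(
            Segment(plane_specs[p], DegradationConfig(), 1)
            for p in STANDARD_PLANES if p != "3VT"), seed=0)
        frames = generate_video(script, size=(64, 64))
        _, report = run_session(frames, OracleModel(names), protocol)
        assert "3VT" in report.missing_mandatory

    def test_arch_counts_as_extra_non_mandatory(self, plane_specs, protocol,
                                                names):
        script = VideoScript(segments=(
            Segment(plane_specs["Arch"], DegradationConfig(), 2),), seed=0)
        frames = generate_video(script, size=(64, 64))
        _, report = run_session(frames, OracleModel(names), protocol)
        assert report.extra_non_mandatory == ["Arch"]
        assert "Arch" not in report.missing_mandatory

    def test_empty_video_misses_every_mandatory_plane(self, protocol,
                                                      names):
        state = CaptureState()
        report = finalize(state, protocol)
        assert set(report.missing_mandatory) == \
            set(protocol.mandatory_planes)
        assert report.captured == {}

    def test_every_plane_in_exactly_one_bucket(self, plane_specs, protocol,
                                               names):
        rng = np.random.default_rng(11)
        script = random_script(rng, plane_specs)
        frames = generate_video(script, size=(64, 64))
        _, report = run_session(frames, OracleModel(names), protocol)
        for plane in STANDARD_PLANES:
            in_captured = plane in report.captured
            in_missing = plane in report.missing_mandatory
            not_applicable = (not protocol.is_mandatory(plane)
                              and not in_captured)
            assert in_captured + in_missing + not_applicable == 1


class TestOracleModel:
    def test_oracle_reproduces_ground_truth(self, plane_specs, protocol,
                                            names):
        frames = generate_video(VideoScript(segments=(
            Segment(plane_specs["Situs"], DegradationConfig(), 1),),
            seed=4), size=(64, 64))
        out = OracleModel(names).predict(frames[0])
        for name, mask in frames[0].masks.items():
            i = names.index(name)
            assert dice(out.structure_maps[i] > 0.5, mask) == 1.0
        assert out.qs_pred == frames[0].qs_true
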