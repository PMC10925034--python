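"""Dice, outcome classification and accuracy against brute-force oracles."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from echoqc.metrics import (FrameEval, Outcome, accuracy, classify_outcome,
                            dice, false_positive_count, mean_required_dice,
                            report)


def oracle_dice_and_outcome(pred, truth):
    """Independent pixel-enumeration oracle (pure python loops)."""
    inter = p_area = t_area = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = bool(pred[i, j]), bool(truth[i, j])
            p_area += p
            t_area += t
            inter += p and t
    if p_area == 0 and t_area == 0:
        return None, "TN"
    d = 2 * inter / (p_area + t_area)
    if t_area == 0:
        return d, "FP"
    return d, ("TP" if d >= 0.5 else "FN")


mask8 = arrays(bool, (8, 8), elements=st.booleans())


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = b[3, 3] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        """Areas 2 and 2 with overlap 1: 2*1/(2+2) = 0.5."""
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = a[0, 1] = True
        b[0, 1] = b[0, 2] = True
        assert dice(a, b) == 0.5

    def test_both_empty_undefined(self):
        z = np.zeros((4, 4), bool)
        with pytest.raises(ValueError):
            dice(z, z)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4), bool), np.zeros((4, 5), bool))

    @settings(max_examples=300, derandomize=True)
    @given(pred=mask8, truth=mask8)
    def test_matches_pixel_enumeration_oracle(self, pred, truth):
        d_oracle, _ = oracle_dice_and_outcome(pred, truth)
        if d_oracle is None:
            with pytest.raises(ValueError):
                dice(pred, truth)
        else:
            assert dice(pred, truth) == pytest.approx(d_oracle, abs=1e-12)


class TestClassifyOutcome:
    def test_dice_above_half_is_tp(self):
        t = np.zeros((4, 4), bool)
        t[0:2, 0:2] = True
        p = t.copy()
        p[0, 0] = False  # dice = 2*3/(3+4) = 6/7 > 0.5
        assert classify_outcome(p, t).outcome is Outcome.TP

    def test_both_empty_is_tn(self):
        z = np.zeros((4, 4), bool)
        out = classify_outcome(z, z)
        assert out.outcome is Outcome.TN
        assert out.dice is None

    def test_prediction_without_annotation_is_fp(self):
        p = np.zeros((4, 4), bool)
        p[1, 1] = True
        assert classify_outcome(p, np.zeros((4, 4), bool)).outcome is \
            Outcome.FP

    def test_missed_annotation_is_fn(self):
        t = np.zeros((4, 4), bool)
        t[1, 1] = True
        out = classify_outcome(np.zeros((4, 4), bool), t)
        assert out.outcome is Outcome.FN
        assert out.dice == 0.0

    def test_dice_exactly_half_is_tp(self):
        """The TP band is inclusive at 0.5."""
        p = np.zeros((4, 4), bool)
        t = np.zeros((4, 4), bool)
        p[0, 0] = p[0, 1] = True
        t[0, 1] = t[0, 2] = True
        out = classify_outcome(p, t)
        assert out.dice == 0.5
        assert out.outcome is Outcome.TP

    @settings(max_examples=300, derandomize=True)
    @given(pred=mask8, truth=mask8)
    def test_matches_oracle_and_is_exhaustive(self, pred, truth):
        _, label = oracle_dice_and_outcome(pred, truth)
        assert classify_outcome(pred, truth).outcome.value == label


class TestAccuracy:
    def test_known_compositions(self):
        assert accuracy({"TP": 3, "TN": 1, "FN": 1, "FP": 0}) == 0.8
        assert accuracy({"TP": 5}) == 1.0
        assert accuracy({"TP": 1, "TN": 1, "FN": 1, "FP": 1}) == 0.5

    def test_exact_rational_arithmetic(self):
        # 1/3 is not representable in binary floating point; the count
        # ratio must still be the closest double to the true rational
        assert accuracy({"TP": 1, "FN": 2}) == float(Fraction(1, 3))

    def test_permutation_invariance(self):
        outcomes = [Outcome.TP, Outcome.FN, Outcome.TN, Outcome.FP,
                    Outcome.TP]
        assert accuracy(outcomes) == accuracy(list(reversed(outcomes)))

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            accuracy([])


def _frame(plane, qs, pred_area, true_area, structure, shape=(8, 8)):
    pred = np.zeros(shape, bool)
    truth = np.zeros(shape, bool)
    pred[:pred_area, 0] = True
    truth[:true_area, 0] = True
    return FrameEval(plane=plane, qs_true=qs,
                     pred_masks={structure: pred} if pred_area else {},
                     true_masks={structure: truth} if true_area else {})


class TestReport:
    def test_single_plane_all_tp(self, protocol):
        s = protocol.required("Situs")[0]
        frames = [_frame("Situs", 8, 4, 4, s) for _ in range(5)]
        rep = report(frames, protocol)
        mean, sd, n = rep.per_plane["Situs"]
        row = rep.per_structure.set_index("structure").loc[s]
        assert row["TP"] == 5 and row["accuracy"] == 1.0
        assert n == 5
        # the other required Situs features are all-empty on both sides: TN
        assert mean == 1.0 and sd == 0.0

    def test_qs_threshold_excludes_low_quality_frames(self, protocol):
        s = protocol.required("4CV")[0]
        good = [_frame("4CV", 8, 4, 4, s) for _ in range(3)]
        bad = [_frame("4CV", 2, 0, 4, s) for _ in range(3)]  # FN frames
        rep_all = report(good + bad, protocol)
        rep_hi = report(good + bad, protocol, qs_threshold=6)
        assert rep_hi.n_images == 3
        assert rep_hi.overall >= rep_all.overall

    def test_unreached_threshold_flags_plane_missing(self, protocol):
        s = protocol.required("4CV")[0]
        frames = [_frame("4CV", 5, 4, 4, s)]
        rep = report(frames, protocol, qs_threshold=10)
        assert "4CV" in rep.missing_planes

    def test_cross_plane_frames_do_not_inflate_tn(self, protocol):
        s4 = protocol.required("4CV")[0]
        frames = [_frame("4CV", 8, 4, 4, s4),
                  _frame("Situs", 8, 4, 4, protocol.required("Situs")[0])]
        rep = report(frames, protocol)
        row = rep.per_structure.set_index("structure").loc[s4]
        assert row["n"] == 1  # the Situs frame contributes nothing to 4CV

    def test_invalid_threshold_rejected(self, protocol):
        with pytest.raises(ValueError):
            report([], protocol, qs_threshold=11)


class TestAggregates:
    def test_false_positive_count(self):
        frames = [_frame("NonHeart", 5, 3, 0, "stomach"),
                  _frame("NonHeart", 5, 0, 0, "stomach")]
        assert false_positive_count(frames, ["stomach"]) == 1

    def test_mean_required_dice_counts_missing_as_zero(self, protocol):
        s = protocol.required("Situs")[0]
        hit = _frame("Situs", 8, 4, 4, s)      # dice 1
        miss = _frame("Situs", 8, 0, 4, s)     # dice 0
        val = mean_required_dice([hit, miss], protocol)
        # only pairs with non-empty truth are scored: (1 + 0) / 2
        assert val == pytest.approx(0.5)
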