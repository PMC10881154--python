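"""Spindle-angle geometry: tangents, angles, bins, and live-track classes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spindlestats.angle_geometry import (
    AngleSample,
    BasementMembraneTrace,
    DivisionTrack,
    PoleAnnotation,
    bin_angle,
    classify_reintegration,
    distribution_summary,
    local_tangent,
    spindle_angle,
    t0_t60_resolution,
)


class TestLocalTangent:
    @pytest.mark.parametrize(
        "points,query,expected",
        [
            ([(0, 0), (100, 0)], (50, 8), (1, 0)),
            ([(0, 0), (0, 100)], (5, 50), (0, 1)),
            # nearest of the two segments (brute-force checked): vertical one
            ([(0, 0), (10, 0), (10, 10)], (9, 6), (0, 1)),
        ],
    )
    def test_nearest_segment_direction(self, points, query, expected):
        trace = BasementMembraneTrace(points=tuple(points))
        d = local_tangent(trace, query)
        assert d == pytest.approx(expected, abs=1e-12)

    def test_degenerate_trace_rejected(self):
        with pytest.raises(ValueError):
            BasementMembraneTrace(points=((1.0, 1.0), (1.0, 1.0)))


class TestSpindleAngle:
    @pytest.mark.parametrize(
        "pole_b,ref,expected",
        [
            ((10, 0), (1, 0), 0.0),
            ((0, 10), (1, 0), 90.0),
            ((10, 10), (1, 0), 45.0),
            # obtuse raw angle (135°) folds to the acute 45°
            ((10, 10), (0, 1), 45.0),
        ],
    )
    def test_acute_angle_against_reference(self, pole_b, ref, expected):
        ann = PoleAnnotation("d", (0, 0), pole_b, reference=ref)
        assert spindle_angle(ann) == pytest.approx(expected, abs=1e-9)

    def test_coincident_poles_rejected(self):
        with pytest.raises(ValueError):
            PoleAnnotation("d", (1, 2), (1, 2), reference=(1, 0))

    def test_exactly_one_reference_required(self):
        trace = BasementMembraneTrace(points=((0, 0), (10, 0)))
        with pytest.raises(ValueError):
            PoleAnnotation("d", (0, 0), (1, 0), reference=(1, 0), trace=trace)
        with pytest.raises(ValueError):
            PoleAnnotation("d", (0, 0), (1, 0))

    def test_local_tangent_reference_from_trace(self):
        # pole axis at 45° to a locally vertical membrane segment
        trace = BasementMembraneTrace(points=((0, 0), (10, 0), (10, 10)))
        ann = PoleAnnotation("d", (8, 5), (10, 7), trace=trace)
        assert spindle_angle(ann) == pytest.approx(45.0, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_invariance_under_swap_negation_and_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 2)) * 10
        if np.allclose(a, b):
            b = a + 1.0
        ref = rng.normal(size=2)
        if np.allclose(ref, 0):
            ref = np.array([1.0, 0.0])
        base = spindle_angle(PoleAnnotation("d", tuple(a), tuple(b), reference=tuple(ref)))
        swapped = spindle_angle(PoleAnnotation("d", tuple(b), tuple(a), reference=tuple(ref)))
        negated = spindle_angle(PoleAnnotation("d", tuple(a), tuple(b), reference=tuple(-ref)))
        theta = rng.uniform(0, 2 * math.pi)
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        shift = rng.normal(size=2) * 100
        moved = spindle_angle(
            PoleAnnotation("d", tuple(rot @ a + shift), tuple(rot @ b + shift),
                           reference=tuple(rot @ ref))
        )
        assert base == pytest.approx(swapped, abs=1e-9)
        assert base == pytest.approx(negated, abs=1e-9)
        assert base == pytest.approx(moved, abs=1e-9)


class TestBinning:
    @pytest.mark.parametrize(
        "angle,expected",
        [
            (30.0, "parallel"),  # parallel bin is closed at 30°
            (60.0, "perpendicular"),  # perpendicular bin is closed at 60°
            (45.0, "oblique"),
            (0.0, "parallel"),
            (90.0, "perpendicular"),
            (30.0000001, "oblique"),
            (59.9999999, "oblique"),
        ],
    )
    def test_bin_boundaries(self, angle, expected):
        assert bin_angle(angle) == expected

    def test_out_of_domain_rejected(self):
        for bad in (-1.0, 90.1):
            with pytest.raises(ValueError):
                bin_angle(bad)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0.0, 90.0))
    def test_partition(self, angle):
        assert bin_angle(angle) in {"parallel", "oblique", "perpendicular"}


class TestDistributionSummary:
    def test_direct_count(self):
        s = distribution_summary(AngleSample("c", (10, 20, 40, 70)))
        assert s.pct_parallel == 50.0
        assert s.pct_oblique == 25.0
        assert s.pct_perpendicular == 25.0
        assert s.median == 30.0

    def test_all_parallel(self):
        s = distribution_summary(AngleSample("c", (0.0, 0.0, 0.0)))
        assert s.pct_parallel == 100.0

    def test_constructed_bin_counts_match_wild_type_proportions(self, rng):
        # 36 parallel + 6 oblique + 3 perpendicular out of n = 45
        angles = np.concatenate([
            rng.uniform(0, 30, 36), rng.uniform(30.0001, 59.9999, 6),
            rng.uniform(60, 90, 3),
        ])
        s = distribution_summary(AngleSample("wt", tuple(angles)))
        assert s.pct_parallel == pytest.approx(80.0)
        assert s.pct_oblique == pytest.approx(100 * 6 / 45)
        assert s.pct_perpendicular == pytest.approx(100 * 3 / 45)

    def test_percentages_sum_to_100_and_quartiles_ordered(self, rng):
        s = distribution_summary(AngleSample("c", tuple(rng.uniform(0, 90, 57))))
        assert s.pct_parallel + s.pct_oblique + s.pct_perpendicular == pytest.approx(100.0)
        assert s.q25 <= s.median <= s.q75

    def test_self_concatenation_invariance(self, rng):
        angles = tuple(rng.uniform(0, 90, 31))
        one = distribution_summary(AngleSample("c", angles))
        two = distribution_summary(AngleSample("c", angles + angles))
        assert one.pct_parallel == two.pct_parallel
        assert one.pct_oblique == two.pct_oblique
        assert one.pct_perpendicular == two.pct_perpendicular
        assert one.median == pytest.approx(two.median, abs=1e-9)
        # linearly interpolated quartiles shift by at most a fraction of one
        # inter-order-statistic gap when the sample is duplicated
        assert one.q25 == pytest.approx(two.q25, abs=1.0)
        assert one.q75 == pytest.approx(two.q75, abs=1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            AngleSample("c", ())


class TestTrackClassification:
    @pytest.mark.parametrize(
        "t0,t60,expected",
        [
            (35.0, 10.0, "resolved"),
            (35.0, 33.0, "persistent"),
            (10.0, 12.0, "planar_at_onset"),
            (35.0, None, "censored"),
        ],
    )
    def test_t0_t60_resolution(self, t0, t60, expected):
        track = DivisionTrack("d", angle_t0=t0, angle_t60=t60)
        assert t0_t60_resolution(track, planar_threshold=20.0) == expected

    def test_reintegrated_within_window(self):
        # suprabasal for 40 frames (200 min), basal thereafter; 10 h track
        layers = ("suprabasal",) * 41 + ("basal",) * 80
        track = DivisionTrack("d", 35.0, 30.0, {"a": ("basal",) * 121, "b": layers})
        assert classify_reintegration(track, window_h=6.0) == "reintegrated"

    def test_retained_when_track_outlasts_window(self):
        layers = ("suprabasal",) * 97  # 8 h at 5-min frames
        track = DivisionTrack("d", 35.0, 30.0, {"b": layers})
        assert classify_reintegration(track, window_h=6.0) == "retained"

    def test_censored_when_track_too_short(self):
        layers = ("suprabasal",) * 24  # < 6 h, no transition
        track = DivisionTrack("d", 35.0, 30.0, {"b": layers})
        assert classify_reintegration(track, window_h=6.0) == "censored"

    def test_error_without_suprabasal_daughter(self):
        track = DivisionTrack("d", 10.0, 5.0, {"a": ("basal",) * 10})
        with pytest.raises(ValueError):
            classify_reintegration(track)

    def test_programmed_cohort_recovered_exactly(self):
        """2 of 5 suprabasal daughters programmed to descend are the 2 found."""
        tracks = {}
        for i in range(5):
            if i < 2:
                layers = ("suprabasal",) * 30 + ("basal",) * 91
            else:
                layers = ("suprabasal",) * 121
            tracks[f"d{i}"] = DivisionTrack(f"d{i}", 40.0, 35.0, {"b": layers})
        classes = {k: classify_reintegration(t, 6.0) for k, t in tracks.items()}
        assert [k for k, v in classes.items() if v == "reintegrated"] == ["d0", "d1"]
        assert all(v == "retained" for k, v in classes.items() if k in ("d2", "d3", "d4"))
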