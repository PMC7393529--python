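"""Kinematic profiles and the 33-feature extractor, against closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import facekin as fk
from facekin.errors import (
    DegenerateGeometryError,
    InvalidArgumentError,
    InvalidStateError,
)
from facekin.features import FEATURE_NAMES


class TestKinematicProfile:
    def test_constant_track_is_all_zero(self):
        p = fk.compute_kinematic_profile(np.full(10, 55.0), fps=30)
        assert np.all(p.displacement == 0)
        assert np.all(p.velocity == 0)
        assert np.all(p.acceleration == 0)

    def test_linear_rise(self):
        # y(t) = y0 - c t  ->  d = c t, v = c*fps, a = 0
        c, fps, T = 0.8, 30.0, 12
        y = 100 - c * np.arange(T)
        p = fk.compute_kinematic_profile(y, fps=fps)
        assert np.allclose(p.displacement, c * np.arange(T))
        assert np.allclose(p.velocity, c * fps)
        assert np.allclose(p.acceleration, 0, atol=1e-9)

    def test_quadratic_gives_constant_acceleration(self):
        k, fps, T = 0.3, 29.97, 15
        t = np.arange(T, dtype=float)
        y = 100 - 0.5 * k * t ** 2
        p = fk.compute_kinematic_profile(y, fps=fps)
        assert np.allclose(p.acceleration, k * fps * fps)

    def test_aperture_signal_sign(self):
        g = np.array([4.0, 6.0, 9.0])
        p = fk.compute_kinematic_profile(g, fps=30, signal="aperture")
        assert np.all(p.displacement == [0, 2, 5])  # opening positive

    def test_lengths(self):
        p = fk.compute_kinematic_profile(np.arange(9.0), fps=30)
        assert len(p.velocity) == 8 and len(p.acceleration) == 7

    def test_too_few_frames_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fk.compute_kinematic_profile(np.array([1.0, 2.0]), fps=30)


class TestNormalizer:
    def test_point_line_distance(self):
        assert fk.head_size_normalizer((100, 200), (300, 200), (200, 350)) == 150

    def test_oblique_line(self):
        # line through (0,0),(3,4); distance of (3,-4)/nose: |3*(-4)... known 5
        d = fk.head_size_normalizer((0, 0), (6, 8), (7, -1))
        assert d == pytest.approx(abs(6 * -1 - 8 * 7) / 10)

    def test_coincident_eyes_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fk.head_size_normalizer((10, 10), (10, 10), (0, 0))

    def test_nose_on_eye_line_is_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            fk.head_size_normalizer((0, 0), (10, 0), (5, 0))


def _profile(d, fps=30.0):
    y = 100.0 - np.asarray(d, float)
    return fk.compute_kinematic_profile(y, fps=fps)


class TestExtractFeatures:
    def test_resting_face_yields_zero_features(self):
        p = _profile(np.zeros(10))
        fv = fk.extract_features(p, p, p, normalizer=5.0)
        assert np.all(fv.values == 0)

    def test_triangle_closed_form(self):
        # rise to +A at 30% of the token, fall to -B at 80%
        A, B, h, fps = 6.0, 3.0, 2.0, 30.0
        track, _ = fk.synth_trajectory("triangle", frames=11, fps=fps,
                                       amplitude=A, trough=B,
                                       peak_time=0.3, trough_time=0.8)
        p = fk.compute_kinematic_profile(track, fps=fps)
        fv = fk.extract_features(p, p, p, normalizer=h)
        assert fv[1] == pytest.approx(A / h)            # max head raise
        assert fv[2] == pytest.approx(B / h)            # max head lower
        assert fv[13] == pytest.approx(0.3)             # time of max raise
        assert fv[14] == pytest.approx(0.8)             # time of max lower
        # largest second difference sits at the peak: slope change from
        # +A/3 to -(A+B)/5 per frame
        kink = (A / 3 + (A + B) / 5) * fps * fps / h
        assert fv[27] == pytest.approx(kink)

    def test_exactly_33_named_features(self):
        p = _profile(np.zeros(5))
        fv = fk.extract_features(p, p, p, normalizer=1.0)
        assert fv.values.shape == (33,)
        assert len(FEATURE_NAMES) == 33
        assert len(set(FEATURE_NAMES)) == 33

    def test_time_features_in_unit_interval_distances_nonnegative(self):
        rng = np.random.default_rng(4)
        p = _profile(rng.normal(0, 3, 40))
        fv = fk.extract_features(p, p, p, normalizer=2.0)
        times = fv.values[12:24]
        assert np.all((times >= 0) & (times <= 1))
        assert np.all(fv.values[:12] >= 0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0, 4, 30)
        for s in (2.0, 17.3):
            a = fk.extract_features(_profile(d), _profile(d), _profile(d),
                                    normalizer=3.0)
            b = fk.extract_features(_profile(s * d), _profile(s * d),
                                    _profile(s * d), normalizer=3.0 * s)
            assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_horizontal_motion_is_ignored(self):
        rng = np.random.default_rng(8)
        T = 25
        ys = 100 + np.cumsum(rng.normal(0, 1, T))
        base = np.column_stack([np.full(T, 50.0), ys])
        jittered = base.copy()
        jittered[:, 0] += rng.normal(0, 10, T)
        pa = fk.compute_kinematic_profile(base, fps=30)
        pb = fk.compute_kinematic_profile(jittered, fps=30)
        fa = fk.extract_features(pa, pa, pa, normalizer=2.0)
        fb = fk.extract_features(pb, pb, pb, normalizer=2.0)
        assert np.array_equal(fa.values, fb.values)

    def test_time_reversal_swaps_raising_and_lowering(self):
        # a profile with d(0) = d(T-1) = 0: reversal maps the raising
        # extremum onto the lowering one and mirrors its relative time
        track, _ = fk.synth_trajectory("triangle", frames=21, fps=30,
                                       amplitude=5, trough=2,
                                       peak_time=0.25, trough_time=0.75)
        d = track[0] - track
        fwd = fk.extract_features(_profile(d), _profile(d), _profile(d), 1.0)
        rev_d = -d[::-1]
        rev = fk.extract_features(_profile(rev_d), _profile(rev_d),
                                  _profile(rev_d), 1.0)
        assert rev[1] == pytest.approx(fwd[2])
        assert rev[2] == pytest.approx(fwd[1])
        assert rev[13] == pytest.approx(1 - fwd[14])
        assert rev[14] == pytest.approx(1 - fwd[13])

    def test_bad_normalizer_rejected(self):
        p = _profile(np.zeros(5))
        with pytest.raises(InvalidArgumentError):
            fk.extract_features(p, p, p, normalizer=0.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("kind,kwargs", [
        ("triangle", dict(amplitude=6, trough=3, peak_time=0.3, trough_time=0.8)),
        ("triangle", dict(amplitude=2.5, trough=8, peak_time=0.25, trough_time=0.7)),
        ("sinusoid", dict(amplitude=5, period=17.3)),
        ("sinusoid", dict(amplitude=0.8, period=9.1)),
    ])
    @pytest.mark.parametrize("frames", [11, 31, 60])
    def test_extractor_matches_plain_loop_reference(self, kind, kwargs, frames):
        track, oracle = fk.synth_trajectory(kind, frames=frames, fps=29.97,
                                            normalizer=7.3, **kwargs)
        p = fk.compute_kinematic_profile(track, fps=29.97)
        fv = fk.extract_features(p, p, p, normalizer=7.3)
        np.testing.assert_allclose(fv.values, oracle.values, rtol=1e-9,
                                   atol=1e-12)

    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=3,
                    max_size=40),
           st.floats(min_value=0.5, max_value=20))
    @settings(max_examples=60, deadline=None)
    def test_random_trajectories_match_reference(self, d, normalizer):
        from facekin.synth import _reference_roi_stats

        d = [0.0] + d[1:]  # displacement starts at zero by definition
        y = 100.0 - np.asarray(d)
        p = fk.compute_kinematic_profile(y, fps=29.97)
        fv = fk.extract_features(p, p, p, normalizer=normalizer)
        ref = _reference_roi_stats([float(y[0]) - float(v) for v in y],
                                   29.97, normalizer)
        np.testing.assert_allclose(fv.values[:4], ref[:4], rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(fv.values[12:16], ref[4:8], rtol=1e-9,
                                   atol=1e-12)
        np.testing.assert_allclose(fv.values[24:27], ref[8:11], rtol=1e-9,
                                   atol=1e-12)


class TestUnitConversion:
    def test_unit_head_size_relabels_only(self):
        p = _profile([0, 2, 5, 1, -3])
        fv = fk.extract_features(p, p, p, normalizer=2.0)
        mm = fk.convert_to_mm(fv, head_size_mm=1.0)
        assert mm.units == "mm"
        assert np.array_equal(mm.values, fv.values)

    def test_distance_scaling(self):
        p = _profile([0, 2, 5, 1, -3])
        fv = fk.extract_features(p, p, p, normalizer=20.0)
        mm = fk.convert_to_mm(fv, head_size_mm=80.0)
        assert mm[1] == pytest.approx(fv[1] * 80.0)

    def test_time_features_untouched(self):
        p = _profile([0, 2, 5, 1, -3])
        fv = fk.extract_features(p, p, p, normalizer=2.0)
        mm = fk.convert_to_mm(fv, head_size_mm=120.0)
        assert np.array_equal(mm.values[12:24], fv.values[12:24])

    def test_double_conversion_rejected(self):
        p = _profile([0, 1, 2])
        fv = fk.extract_features(p, p, p, normalizer=2.0)
        mm = fk.convert_to_mm(fv, head_size_mm=80.0)
        with pytest.raises(InvalidStateError):
            fk.convert_to_mm(mm, head_size_mm=80.0)
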