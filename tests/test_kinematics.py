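"""Gaze reconstruction, ray-plane intersection and AOI labeling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gazescan as gs
from gazescan.kinematics import (
    PlanarRect,
    angles_to_direction,
    direction_to_angles,
    intersect_plane,
    rotation_matrix,
)

from conftest import make_trace

angles = st.floats(-80.0, 80.0)


@given(yaw=st.floats(-179.0, 179.0), pitch=st.floats(-89.0, 89.0))
def test_direction_round_trip(yaw, pitch):
    """direction -> (yaw, pitch) -> direction is the identity."""
    d = angles_to_direction(yaw, pitch)
    y2, p2 = direction_to_angles(d)
    assert np.allclose([y2, p2], [yaw, pitch], atol=1e-9)


def test_rotation_matrix_maps_forward_to_direction():
    r = rotation_matrix(33.0, -21.0)
    assert np.allclose(r @ [0, 0, 1], angles_to_direction(33.0, -21.0))
    assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)


class TestReconstructGaze:
    def test_primary_eye_position_gives_head_angles(self):
        eye = make_trace("eye", "head_frame", [0.0], [0.0])
        head = make_trace("head", "world_frame", [20.0], [-5.0])
        for mode in ("compose", "additive"):
            g = gs.reconstruct_gaze(eye, head, mode)
            assert g.yaw[0] == pytest.approx(20.0, abs=1e-12)
            assert g.pitch[0] == pytest.approx(-5.0, abs=1e-12)

    def test_zero_head_gives_eye_angles(self):
        eye = make_trace("eye", "head_frame", [10.0, -30.0], [0.0, 12.0])
        head = make_trace("head", "world_frame", [0.0, 0.0], [0.0, 0.0])
        for mode in ("compose", "additive"):
            g = gs.reconstruct_gaze(eye, head, mode)
            assert np.allclose(g.yaw, eye.yaw, atol=1e-12)
            assert np.allclose(g.pitch, eye.pitch, atol=1e-12)

    def test_compose_matches_rotation_matrix_oracle(self):
        """Independent oracle: build both rotation matrices, multiply,
        extract yaw/pitch from the composed forward vector."""
        eye = make_trace("eye", "head_frame", [10.0], [5.0])
        head = make_trace("head", "world_frame", [20.0], [-10.0])
        g = gs.reconstruct_gaze(eye, head, "compose")
        d = rotation_matrix(20.0, -10.0) @ angles_to_direction(10.0, 5.0)
        yaw_o, pitch_o = direction_to_angles(d)
        assert g.yaw[0] == pytest.approx(yaw_o, abs=1e-12)
        assert g.pitch[0] == pytest.approx(pitch_o, abs=1e-12)

    @given(
        ey=st.floats(-10, 10), ep=st.floats(-10, 10),
        hy=st.floats(-10, 10), hp=st.floats(-10, 10),
    )
    def test_compose_additive_agree_for_small_angles(self, ey, ep, hy, hp):
        eye = make_trace("eye", "head_frame", [ey], [ep])
        head = make_trace("head", "world_frame", [hy], [hp])
        gc = gs.reconstruct_gaze(eye, head, "compose")
        ga = gs.reconstruct_gaze(eye, head, "additive")
        assert abs(gc.yaw[0] - ga.yaw[0]) < 0.5
        assert abs(gc.pitch[0] - ga.pitch[0]) < 0.5

    @given(ey=angles, hy=angles)
    def test_yaw_only_closure(self, ey, hy):
        """With pitch = 0 both modes coincide: yaw rotations commute."""
        eye = make_trace("eye", "head_frame", [ey], [0.0])
        head = make_trace("head", "world_frame", [hy], [0.0])
        gc = gs.reconstruct_gaze(eye, head, "compose")
        ga = gs.reconstruct_gaze(eye, head, "additive")
        # compose wraps to (-180, 180]; compare directions, not raw angles
        assert np.allclose(
            angles_to_direction(gc.yaw[0], gc.pitch[0]),
            angles_to_direction(ga.yaw[0], ga.pitch[0]),
            atol=1e-9,
        )

    def test_frame_mismatch_rejected(self):
        head = make_trace("head", "world_frame", [0.0], [0.0])
        with pytest.raises(ValueError):
            gs.reconstruct_gaze(head, head)

    def test_invalid_samples_propagate(self):
        eye = make_trace("eye", "head_frame", [1.0, 2.0], [0.0, 0.0],
                         valid=np.array([True, False]))
        head = make_trace("head", "world_frame", [0.0, 0.0], [0.0, 0.0])
        g = gs.reconstruct_gaze(eye, head)
        assert list(g.valid) == [True, False]


class TestIntersectPlane:
    RECT = PlanarRect.from_corners((-1, -1, 2), (1, -1, 2), (-1, 1, 2))

    def test_axis_aligned_hit(self):
        assert np.allclose(
            intersect_plane((0, 0, 0), (0, 0, 1.0), self.RECT), [0, 0, 2]
        )

    def test_behind_origin_is_none(self):
        assert intersect_plane((0, 0, 0), (0, 0, -1.0), self.RECT) is None

    def test_parallel_is_none(self):
        assert intersect_plane((0, 0, 0), (1.0, 0, 0), self.RECT) is None

    def test_outside_bounds_is_none(self):
        d = np.array([3.0, 0, 2.0])
        d /= np.linalg.norm(d)
        assert intersect_plane((0, 0, 0), d, self.RECT) is None

    @given(
        yaw=st.floats(-20, 20), pitch=st.floats(-20, 20),
        tilt=st.floats(-30, 30),
    )
    def test_oblique_matches_algebraic_oracle(self, yaw, pitch, tilt):
        """Parametric-line / plane-equation oracle to 1e-9 m."""
        rect = PlanarRect.facing((0, 0, 0), (2.0, tilt, 10.0), 5.0, 5.0)
        d = angles_to_direction(yaw, pitch)
        hit = intersect_plane((0, 0, 0), d, rect)
        n = np.cross(rect.e1, rect.e2)
        tau = (rect.origin @ n) / (d @ n)  # oracle: solve o + tau d on plane
        oracle = tau * d
        assert hit is not None
        assert np.allclose(hit, oracle, atol=1e-9)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            intersect_plane((0, 0, 0), (0, 0, 2.0), self.RECT)


class TestAssignAoi:
    def test_canonical_directions(self):
        geom = gs.SceneGeometry.default()
        gaze = make_trace(
            "gaze", "world_frame", [0.0, 20.0, 0.0, -40.0], [0.0, -15.0, 80.0, 25.0]
        )
        labels = gs.assign_aoi(gaze, geom)
        assert list(labels) == ["central_screen", "device", "other", "other"]

    def test_every_sample_gets_exactly_one_label(self, short_session):
        gaze = gs.reconstruct_gaze(short_session.eye, short_session.head)
        labels = gs.assign_aoi(gaze, gs.SceneGeometry.default())
        assert len(labels) == len(gaze)
        assert set(labels) <= {"central_screen", "device", "other"}

    def test_invalid_samples_are_other(self):
        gaze = make_trace("gaze", "world_frame", [0.0], [0.0],
                          valid=np.array([False]))
        assert gs.assign_aoi(gaze, gs.SceneGeometry.default())[0] == "other"


class TestResampleAndSync:
    def test_aligned_traces_unchanged(self):
        t = np.arange(1200) / 120.0
        eye = make_trace("eye", "head_frame", np.sin(t), np.cos(t))
        head = make_trace("head", "world_frame", np.sin(t), np.cos(t))
        e2, h2 = gs.resample_and_sync(eye, head, 120.0)
        assert np.allclose(e2.yaw, eye.yaw, atol=1e-12)
        assert np.allclose(h2.pitch, head.pitch, atol=1e-12)

    def test_half_period_offset_midpoint_average(self):
        """For linear signals the interpolated midpoint is the neighbor mean."""
        rate = 120.0
        t = np.arange(600) / rate
        eye = gs.EffectorTrace("eye", "head_frame", t, 2.0 * t, 3.0 * t)
        head = gs.EffectorTrace(
            "head", "world_frame", t + 0.5 / rate, 2.0 * (t + 0.5 / rate), np.zeros_like(t)
        )
        e2, h2 = gs.resample_and_sync(eye, head, rate)
        assert np.allclose(e2.t, h2.t)
        assert np.allclose(e2.yaw, 2.0 * e2.t, atol=1e-9)
        assert np.allclose(h2.yaw, 2.0 * h2.t, atol=1e-9)

    def test_overlap_sample_count(self):
        t = np.arange(1320) / 120.0  # 11 s
        eye = make_trace("eye", "head_frame", np.zeros(1320), np.zeros(1320))
        head = gs.EffectorTrace(
            "head", "world_frame", t + 1.0, np.zeros(1320), np.zeros(1320)
        )
        e2, _ = gs.resample_and_sync(eye, head, 120.0)
        # overlap is [1.0, 1319/120] s: 1199 full 120 Hz steps -> 1200 samples
        assert len(e2) == 1200
        assert e2.t[0] == pytest.approx(1.0)

    def test_no_overlap_rejected(self):
        eye = make_trace("eye", "head_frame", [0.0, 1.0], [0.0, 0.0])
        head = gs.EffectorTrace(
            "head", "world_frame", [10.0, 11.0], [0.0, 0.0], [0.0, 0.0]
        )
        with pytest.raises(ValueError, match="overlap"):
            gs.resample_and_sync(eye, head)

    def test_long_gaps_flagged_invalid(self):
        t = np.arange(240) / 120.0
        valid = np.ones(240, dtype=bool)
        valid[60:180] = False  # a 1 s dropout
        eye = make_trace("eye", "head_frame", np.zeros(240), np.zeros(240), valid=valid)
        head = make_trace("head", "world_frame", np.zeros(240), np.zeros(240))
        e2, _ = gs.resample_and_sync(eye, head, 120.0, max_gap_s=0.1)
        assert not e2.valid[120]
        assert e2.valid[10]
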