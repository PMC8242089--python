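import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foceamap import gaze


class TestRotations:
    @pytest.mark.parametrize("r", [gaze._rx(33.0), gaze._ry(-70.0), gaze._rz(120.0)])
    def test_orthonormal(self, r):
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0)

    def test_rz_quarter_turn(self):
        assert np.allclose(gaze._rz(90.0) @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_zero_head_rotation_is_identity(self):
        assert np.allclose(gaze.head_rotation(0.0, 0.0), np.eye(3), atol=1e-12)

    @given(azi=st.floats(-179.0, 179.0), ele=st.floats(-89.0, 89.0))
    @settings(deadline=None, max_examples=50)
    def test_direction_round_trip(self, azi, ele):
        a, e = gaze.vector_angles(gaze.direction_vector(azi, ele))
        assert a == pytest.approx(azi, abs=1e-9)
        assert e == pytest.approx(ele, abs=1e-9)


class TestTorsion:
    def test_linear_in_pitch(self):
        assert gaze.torsion_from_pitch(40.0) == pytest.approx(13.0)
        assert gaze.torsion_from_pitch(0.0) == 0.0
        assert gaze.torsion_from_pitch(-40.0) == pytest.approx(-13.0)

    def test_array_input(self):
        out = gaze.torsion_from_pitch(np.array([0.0, 40.0]))
        assert out.tolist() == [0.0, 13.0]


class TestFocealProjection:
    def test_reference_projects_to_focea(self):
        geom = gaze.EyeGeometry()
        for eye in ("left", "right"):
            a, e = gaze.foceal_projection(0.0, 0.0, 0.0, 0.0, geom, eye)
            assert a == pytest.approx(0.0, abs=1e-9)
            assert e == pytest.approx(20.0, abs=1e-9)

    def test_left_right_mirror_symmetry(self):
        # with torsion disabled the two eyes are mirror images through the
        # sagittal plane; pitch-coupled torsion (same sign in mirrored
        # sockets) deliberately breaks this symmetry
        geom = gaze.EyeGeometry()
        aL, eL = gaze.foceal_projection(0.0, 0.0, 25.0, 0.0, geom, "left",
                                        torsion_gain=0.0)
        aR, eR = gaze.foceal_projection(0.0, 0.0, 25.0, 0.0, geom, "right",
                                        torsion_gain=0.0)
        assert aL == pytest.approx(-aR, abs=1e-9)
        assert eL == pytest.approx(eR, abs=1e-9)

    def test_gimbal_pitch_returns_nan(self):
        geom = gaze.EyeGeometry()
        a, e = gaze.foceal_projection(0.0, 0.0, 90.0, 0.0, geom, "left")
        assert np.isnan(a) and np.isnan(e)

    def test_array_shapes(self):
        geom = gaze.EyeGeometry()
        a, e = gaze.foceal_projection(
            np.zeros(5), np.zeros(5), np.linspace(-40, 40, 5), 0.0, geom, "left"
        )
        assert a.shape == e.shape == (5,)

    def test_compensation_restores_focea(self):
        geom = gaze.EyeGeometry()
        pitches = np.array([-30.0, 0.0, 30.0])
        h, v = gaze.compensatory_eye_positions(pitches, 5.0, geom, "left")
        a, e = gaze.foceal_projection(h, v, pitches, 5.0, geom, "left")
        assert np.allclose(a, 0.0, atol=1e-6)
        assert np.allclose(e, 20.0, atol=1e-6)

    def test_compensation_error_bounded_at_extreme_pitch(self):
        # with torsion slaved to pitch the two free eye angles cannot always
        # reach the target exactly; the best achievable error stays small
        geom = gaze.EyeGeometry()
        pitches = np.array([-45.0, 45.0])
        h, v = gaze.compensatory_eye_positions(pitches, 5.0, geom, "left")
        a, e = gaze.foceal_projection(h, v, pitches, 5.0, geom, "left")
        assert np.max(np.abs(a - 0.0)) < 1.0
        assert np.max(np.abs(e - 20.0)) < 1.0


class TestCircularStats:
    def test_mean_wraps(self):
        assert gaze.circular_mean([350.0, 10.0]) == pytest.approx(0.0, abs=1e-9)

    def test_sd_of_tight_cluster(self):
        sd = gaze.circular_sd([-10.0, 10.0])
        assert sd == pytest.approx(10.0, abs=0.2)  # ~ linear SD for small spread

    def test_sd_nonnegative_and_zero_for_point_mass(self):
        sd = gaze.circular_sd([42.0, 42.0, 42.0])
        assert sd == 0.0
        assert not np.signbit(sd)


class TestProjectionHistogram:
    def test_point_mass(self):
        counts, _, ele_centers, stats = gaze.projection_histogram(
            np.zeros(100), np.full(100, 20.0)
        )
        assert counts.sum() == 100
        assert stats["circ_mean_elevation"] == pytest.approx(20.0, abs=0.6)
        assert stats["circ_sd_elevation"] == pytest.approx(0.0, abs=1e-6)

    def test_eye_offset_shifts_apparent_direction(self):
        # a 15-cm vector from an eye 5 cm up appears higher from the origin
        _, _, _, stats0 = gaze.projection_histogram(np.zeros(10), np.zeros(10))
        _, _, _, stats1 = gaze.projection_histogram(
            np.zeros(10), np.zeros(10),
            eye_positions_cm=np.tile([0.0, 0.0, 5.0], (10, 1)),
        )
        assert stats1["circ_mean_elevation"] > stats0["circ_mean_elevation"]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            gaze.projection_histogram([np.nan], [np.nan])


class TestStratifiedSample:
    def test_equalizes_joint_histograms(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame(dict(pitch=rng.uniform(-30, 30, 500),
                              roll=rng.uniform(-10, 10, 500)))
        b = pd.DataFrame(dict(pitch=rng.uniform(-10, 50, 400),
                              roll=rng.uniform(-10, 10, 400)))
        out = gaze.stratified_sample({"still": a, "run": b}, bin_deg=10.0)
        for name, df in out.items():
            assert len(df) <= len((a, b)[name == "run"])

        def hist(df):
            pi = np.floor(df["pitch"].to_numpy() / 10.0).astype(int)
            ri = np.floor(df["roll"].to_numpy() / 10.0).astype(int)
            keys, counts = np.unique(list(zip(pi, ri)), axis=0, return_counts=True)
            return {tuple(k): c for k, c in zip(keys, counts)}

        ha, hb = hist(out["still"]), hist(out["run"])
        assert ha == hb

    def test_single_condition_raises(self):
        with pytest.raises(ValueError):
            gaze.stratified_sample({"only": pd.DataFrame(dict(pitch=[0.0], roll=[0.0]))})


class TestLocomotionFilter:
    def test_detects_straight_run(self):
        t = np.arange(0.0, 10.0, 0.1)
        x = np.where(t < 3.0, 0.0, np.where(t < 7.0, (t - 3.0) * 20.0, 80.0))
        body = np.stack([x, np.zeros_like(t)], axis=1)
        intervals, ok = gaze.locomotion_filter(t, body, body.copy())
        assert len(intervals) == 1
        lo, hi = intervals[0]
        assert 2.8 <= lo <= 3.3 and 6.7 <= hi <= 7.2
        assert ok.sum() == pytest.approx(40, abs=4)

    def test_head_motion_excluded(self):
        t = np.arange(0.0, 5.0, 0.1)
        body = np.stack([t * 20.0, np.zeros_like(t)], axis=1)
        head = body + np.stack([np.zeros_like(t), np.sin(10 * t) * 2.0], axis=1)
        intervals, ok = gaze.locomotion_filter(t, body, head)
        assert ok.sum() < len(t) / 2


class TestChamber:
    def test_half_width_endpoints(self):
        ch = gaze.ChamberModel()
        assert ch.half_width(0.0) == pytest.approx(3.0)
        assert ch.half_width(18.0) == pytest.approx(12.0)

    def test_eye_camera_height(self):
        ch = gaze.ChamberModel()
        assert ch.eye_camera_height(0.0) == pytest.approx(5.0)
        assert ch.eye_camera_height(90.0) == pytest.approx(7.0)
        assert ch.eye_camera_height(-90.0) == pytest.approx(3.0)

    def test_ray_hits_screen_wall(self):
        ch = gaze.ChamberModel()
        p = ch.ray_intersection([9.0, 0.0, 5.0], [1.0, 0.0, 0.0])
        assert np.allclose(p, [18.0, 0.0, 5.0], atol=1e-6)

    def test_ray_hits_ceiling(self):
        ch = gaze.ChamberModel()
        p = ch.ray_intersection([9.0, 0.0, 5.0], [0.0, 0.0, 1.0])
        assert np.allclose(p, [9.0, 0.0, 20.0], atol=1e-6)

    def test_ray_hits_slanted_side_wall(self):
        ch = gaze.ChamberModel()
        p = ch.ray_intersection([9.0, 0.0, 5.0], [0.0, 1.0, 0.0])
        assert np.allclose(p, [9.0, ch.half_width(9.0), 5.0], atol=1e-6)

    def test_ray_matches_marching_oracle(self):
        ch = gaze.ChamberModel()
        o = np.array([4.0, 1.0, 3.0])
        d = np.array([0.8, 0.5, 0.33])
        d = d / np.linalg.norm(d)
        p = ch.ray_intersection(o, d)
        # march until the point leaves the chamber
        ts = np.arange(0.0, 60.0, 1e-4)
        inside = np.array([ch.contains(o + t * d, tol=1e-9) for t in ts])
        t_exit = ts[np.argmin(inside)]
        assert np.allclose(p, o + t_exit * d, atol=5e-3)


class TestEyeWorldPositions:
    def test_heading_zero_offsets(self):
        ch = gaze.ChamberModel()
        geom = gaze.EyeGeometry()
        track = pd.DataFrame(dict(x=[9.0], y=[0.0], heading_deg=[0.0], pitch=[0.0]))
        pos = gaze.eye_world_positions(track, ch, geom)
        assert np.allclose(pos["left"][0], [9.0, 0.5, 4.0])
        assert np.allclose(pos["right"][0], [9.0, -0.5, 4.0])


class TestOpticFlow:
    def _track(self, xs):
        n = len(xs)
        return pd.DataFrame(
            dict(
                t=np.arange(n, dtype=float),
                x=np.asarray(xs, dtype=float),
                y=np.zeros(n),
                heading_deg=np.zeros(n),
                pitch=np.zeros(n),
                roll=np.zeros(n),
                eyeL_h=np.zeros(n),
                eyeL_v=np.zeros(n),
                eyeR_h=np.zeros(n),
                eyeR_v=np.zeros(n),
            )
        )

    def test_zero_flow_at_rest(self):
        ch = gaze.ChamberModel()
        geom = gaze.EyeGeometry()
        da, de, n, _, _ = gaze.optic_flow(
            self._track([9.0, 9.0]), ch, geom, "left", spacing=20.0
        )
        ok = n > 0
        assert ok.any()
        assert np.allclose(da[ok], 0.0, atol=1e-9)
        assert np.allclose(de[ok], 0.0, atol=1e-9)

    def test_forward_motion_produces_flow(self):
        ch = gaze.ChamberModel()
        geom = gaze.EyeGeometry()
        da, de, n, _, _ = gaze.optic_flow(
            self._track([8.0, 9.0]), ch, geom, "left", spacing=20.0
        )
        ok = n > 0
        assert np.nanmax(np.abs(da[ok])) > 0.5

    def test_single_frame_raises(self):
        with pytest.raises(ValueError):
            gaze.optic_flow(
                self._track([9.0]), gaze.ChamberModel(), gaze.EyeGeometry(), "left"
            )
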