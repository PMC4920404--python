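"""Scene construction, kinematics, projection, rendering and flow I/O."""

import numpy as np
import pytest

from headingflow.stimulus import (
    OBSERVER_SPEED,
    TABLE1,
    BlankObject,
    CameraModel,
    ObjectTrajectory,
    TrialConfig,
    advance_world,
    apply_laminar_perturbation,
    build_scene,
    flow_sequence,
    horn_schunck,
    object_foe_azimuth,
    object_relative_velocity,
    project_flow,
    read_flo,
    render_frames,
    simulate_worlds,
    write_flo,
    write_flow_text,
)


def make_config(small_camera, condition=None, **kw):
    obj = ObjectTrajectory(**TABLE1[condition]) if condition else None
    defaults = dict(camera=small_camera, obj=obj, dots_per_plane=300, object_dots=64)
    defaults.update(kw)
    return TrialConfig(**defaults)


class TestCamera:
    def test_deg_px_roundtrip(self, small_camera):
        az = np.array([-30.0, -5.0, 0.0, 12.0, 40.0])
        back = small_camera.px_to_deg(small_camera.deg_to_px(az))
        assert np.allclose(back, az, atol=1e-10)

    def test_center_maps_to_straight_ahead(self, small_camera):
        assert small_camera.px_to_deg(small_camera.cx) == pytest.approx(0.0)

    def test_behind_camera_projects_nan(self, small_camera):
        xy = small_camera.project(np.array([[0.0, 0.0, -10.0]]))
        assert np.isnan(xy).all()


class TestSceneConstruction:
    def test_dot_counts_match_printed_configuration(self):
        # two planes of 3000 dots each plus a 320-dot object
        cfg = TrialConfig(obj=ObjectTrajectory(**TABLE1["approach_15"]))
        world = build_scene(cfg)
        assert (world.owner == 0).sum() == 3000
        assert (world.owner == 1).sum() == 3000
        assert (world.owner == -1).sum() == 320

    def test_same_seed_identical(self, small_camera):
        cfg = make_config(small_camera, "approach_15", seed=7)
        a, b = build_scene(cfg), build_scene(cfg)
        assert np.array_equal(a.pos, b.pos)

    def test_object_dots_coplanar(self, small_camera):
        cfg = make_config(small_camera, "approach_15")
        world = build_scene(cfg)
        z = world.pos[world.owner == -1, 2]
        assert np.allclose(z, z[0])

    def test_object_reaching_camera_rejected(self, small_camera):
        bad = ObjectTrajectory(lateral_offset=0, depth=100, speed=200, angle_deg=15)
        with pytest.raises(ValueError, match="depth"):
            TrialConfig(camera=small_camera, obj=bad).validate()


class TestKinematics:
    def test_world_speed_matches_printed_value(self):
        # approach rows are world-frame: |relative + observer| = printed speed
        for name in ("approach_15", "approach_70"):
            obj = ObjectTrajectory(**TABLE1[name])
            v_rel = object_relative_velocity(obj)
            v_world = v_rel + np.array([0.0, 0.0, OBSERVER_SPEED])
            assert np.linalg.norm(v_world) == pytest.approx(obj.speed)

    def test_fixed_depth_keeps_relative_depth(self, small_camera):
        cfg = make_config(small_camera, "fixed_depth")
        worlds = simulate_worlds(cfg)
        depths = [w.object_center[2] for w in worlds]
        assert np.allclose(depths, depths[0])

    def test_retreating_depth_increases_monotonically(self, small_camera):
        cfg = make_config(small_camera, "retreating")
        worlds = simulate_worlds(cfg)
        depths = np.array([w.object_center[2] for w in worlds])
        assert np.all(np.diff(depths) > 0)

    def test_one_frame_displacement(self, small_camera):
        cfg = make_config(small_camera, "approach_15")
        w0 = build_scene(cfg)
        w1 = advance_world(w0, cfg, 1)
        obj = cfg.obj
        moved = w1.object_center - w0.object_center
        # object displaces speed/30 cm per frame along its world trajectory
        v_world = object_relative_velocity(obj) + np.array([0, 0, OBSERVER_SPEED])
        # subtract the observer translation applied as scene motion
        assert np.linalg.norm(moved + [0, 0, OBSERVER_SPEED / 30.0]) == pytest.approx(
            obj.speed / 30.0, rel=1e-9
        )
        assert np.allclose(moved, v_world / 30.0 - [0, 0, OBSERVER_SPEED / 30.0])


class TestObjectFoe:
    def test_half_angle_identity(self):
        # equal object/observer speeds put the object-region FoE at half the
        # trajectory angle, on the side opposite the lateral motion
        assert object_foe_azimuth(
            ObjectTrajectory(**TABLE1["approach_15"])
        ) == pytest.approx(-7.5, abs=1e-9)
        assert object_foe_azimuth(
            ObjectTrajectory(**TABLE1["approach_70"])
        ) == pytest.approx(-35.0, abs=1e-9)

    def test_projected_object_flow_vanishes_at_foe(self, small_camera):
        # empirical cross-check: the rendered object flow really is radial
        # about the analytic singularity
        cfg = make_config(small_camera, "approach_15", object_dots=400)
        worlds = simulate_worlds(cfg)
        f = project_flow(worlds[0], worlds[1], small_camera)
        obj = f.sample_owner == -1
        az = small_camera.px_to_deg(f.sample_xy[obj, 0])
        mag = np.hypot(f.sample_uv[obj, 0], f.sample_uv[obj, 1])
        foe = object_foe_azimuth(cfg.obj)
        near = np.abs(az - foe) < 2.0
        far = np.abs(az - foe) > 6.0
        if near.any() and far.any():
            assert mag[near].mean() < mag[far].mean()

    def test_non_approaching_object_has_no_foe(self):
        with pytest.raises(ValueError):
            object_foe_azimuth(ObjectTrajectory(**TABLE1["retreating"]))


class TestProjection:
    def test_center_flow_near_zero_static_scene(self, small_camera):
        cfg = make_config(small_camera, dots_per_plane=2000)
        worlds = simulate_worlds(cfg)
        f = project_flow(worlds[0], worlds[1], small_camera)
        r = np.hypot(
            f.sample_xy[:, 0] - small_camera.cx, f.sample_xy[:, 1] - small_camera.cy
        )
        mag = np.hypot(f.sample_uv[:, 0], f.sample_uv[:, 1])
        near = r < 3
        if near.any():
            assert mag[near].max() < 0.1

    def test_flow_scales_inversely_with_depth(self, small_camera):
        # a dot at twice the depth at the same image position moves half as fast
        cam = small_camera
        from dataclasses import replace

        from headingflow.stimulus import DotWorld

        pos = np.array([[100.0, 50.0, 500.0], [200.0, 100.0, 1000.0]])
        w0 = DotWorld(pos=pos.copy(), owner=np.zeros(2, dtype=int))
        p1 = pos.copy()
        p1[:, 2] -= OBSERVER_SPEED / 30.0
        w1 = replace(w0, pos=p1)
        f = project_flow(w0, w1, cam)
        mags = np.hypot(f.sample_uv[:, 0], f.sample_uv[:, 1])
        assert mags[0] == pytest.approx(2 * mags[1], rel=0.02)

    def test_opaque_object_occludes_background(self, small_camera):
        cfg = make_config(small_camera, "fixed_depth", dots_per_plane=2000)
        worlds = simulate_worlds(cfg)
        f = project_flow(worlds[0], worlds[1], small_camera)
        # background samples must not project inside the object's footprint
        w = worlds[0]
        oc = w.object_center
        bg = f.sample_owner >= 0
        xy = f.sample_xy[bg]
        z = f.sample_depth[bg]
        # project the object's rectangle corners
        half = w.object_size / 2.0
        corners = small_camera.project(
            np.array(
                [
                    [oc[0] - half, oc[1] - half, oc[2]],
                    [oc[0] + half, oc[1] + half, oc[2]],
                ]
            )
        )
        x0, x1 = sorted(corners[:, 0])
        y0, y1 = sorted(corners[:, 1])
        inside = (
            (xy[:, 0] > x0 + 1)
            & (xy[:, 0] < x1 - 1)
            & (xy[:, 1] > y0 + 1)
            & (xy[:, 1] < y1 - 1)
        )
        assert not np.any(inside & (z > oc[2]))

    def test_blank_object_occludes_but_emits_nothing(self, small_camera):
        blank = BlankObject(lateral=0.0, depth=300.0, width=400.0, height=400.0)
        cfg = make_config(small_camera, blank=blank, dots_per_plane=500)
        worlds = simulate_worlds(cfg)
        frames = render_frames(worlds[:2], small_camera)
        # the blank region occludes everything near the center: no texture
        cy, cx = int(small_camera.cy), int(small_camera.cx)
        assert frames[0][cy - 2 : cy + 3, cx - 2 : cx + 3].max() == 0.0


class TestRendering:
    def test_frame_count_and_range(self, small_camera):
        cfg = make_config(small_camera, dots_per_plane=100)
        worlds = simulate_worlds(cfg)
        frames = render_frames(worlds, small_camera)
        assert frames.shape[0] == 45  # 1.5 s at 30 frames/s
        assert frames.min() >= 0.0 and frames.max() <= 1.0

    def test_empty_world_renders_black(self, small_camera):
        cfg = make_config(small_camera, dots_per_plane=0)
        worlds = simulate_worlds(cfg)[:3]
        frames = render_frames(worlds, small_camera)
        assert frames.max() == 0.0


class TestLaminarPerturbation:
    def _flows(self, small_camera):
        cfg = make_config(small_camera, dots_per_plane=400, n_frames=20)
        return flow_sequence(cfg)

    def test_zero_frames_is_identity(self, small_camera):
        flows = self._flows(small_camera)
        out = apply_laminar_perturbation(flows, 0, 5)
        assert all(np.array_equal(a.u, b.u) for a, b in zip(flows, out))

    def test_exact_window_uniform(self, small_camera):
        flows = self._flows(small_camera)
        out = apply_laminar_perturbation(flows, 5, 8, u=2.0, v=0.0)
        for k, f in enumerate(out):
            if 8 <= k < 13:
                assert np.all(f.u[f.valid] == 2.0)
                assert np.all(f.v[f.valid] == 0.0)
                assert np.allclose(f.sample_uv, [2.0, 0.0])
            else:
                assert np.array_equal(f.u, flows[k].u)

    def test_window_outside_trial_rejected(self, small_camera):
        flows = self._flows(small_camera)
        with pytest.raises(ValueError):
            apply_laminar_perturbation(flows, 10, 15)


class TestHornSchunck:
    def test_uniform_shift_recovered(self, rng):
        # independent oracle: a rigid 1-px rightward shift of a textured
        # frame has known flow (1, 0) everywhere
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.random((40, 48)), 1.5)
        pair = np.stack([img, np.roll(img, 1, axis=1)])
        flow = horn_schunck(pair, alpha=0.1, n_iter=500)[0]
        h, w = img.shape
        inner_u = flow.u[5 : h - 5, 5 : w - 5]
        inner_v = flow.v[5 : h - 5, 5 : w - 5]
        assert inner_u.mean() == pytest.approx(1.0, abs=0.05)
        assert abs(inner_v.mean()) < 0.1

    def test_static_pair_zero_flow(self, rng):
        img = rng.random((20, 20))
        flow = horn_schunck(np.stack([img, img]))[0]
        assert np.abs(flow.u).max() < 1e-9
        assert flow.shape == img.shape

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            horn_schunck(np.zeros((1, 10, 10)))


class TestFlowIO:
    def test_flo_roundtrip(self, small_camera, tmp_path):
        cfg = make_config(small_camera, dots_per_plane=200, n_frames=3)
        f = flow_sequence(cfg)[0]
        path = tmp_path / "f.flo"
        write_flo(path, f)
        u, v = read_flo(path)
        assert np.allclose(u, f.u, atol=1e-6)
        assert np.allclose(v, f.v, atol=1e-6)

    def test_text_dump(self, small_camera, tmp_path):
        cfg = make_config(small_camera, dots_per_plane=50, n_frames=3)
        f = flow_sequence(cfg)[0]
        path = tmp_path / "f.txt"
        write_flow_text(path, f)
        data = np.loadtxt(path)
        assert data.shape == (f.u.size, 5)

    def test_mirror_is_involution(self, small_camera):
        cfg = make_config(small_camera, "approach_15", dots_per_plane=200, n_frames=3)
        f = flow_sequence(cfg)[0]
        g = f.mirrored().mirrored()
        assert np.allclose(g.u, f.u)
        assert np.allclose(g.sample_xy, f.sample_xy)
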