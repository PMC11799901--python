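"""DRR projection, kV simulation, and rigid registration."""

from dataclasses import replace

import numpy as np
import pytest

from sctqa.geometry import Volume
from sctqa.phantom import ErrorMode, PhantomSpec, generate_phantom_pair
from sctqa.positioning import (
    ProjectionGeometry,
    RigidPose,
    ViewGeometry,
    generate_drr,
    positioning_delta,
    register_2d2d,
    register_3d_rigid,
    simulate_kv_pair,
)


@pytest.fixture(scope="module")
def geom():
    return ProjectionGeometry.default_orthogonal()


class TestPose:
    def test_apply_inverse_roundtrip(self):
        pose = RigidPose((2.0, -1.0, 3.0), (4.0, -2.0, 1.5))
        rng = np.random.default_rng(41)
        pts = rng.uniform(-50, 50, (20, 3))
        back = pose.apply_inverse(pose.apply(pts, (1, 2, 3)), (1, 2, 3))
        assert np.allclose(back, pts, atol=1e-12)

    def test_rotation_range_validated(self):
        with pytest.raises(ValueError):
            RigidPose(rotations_deg=(0.0, 190.0, 0.0))

    def test_view_orthogonality_enforced(self):
        v = ViewGeometry((0, 1000, 0), (0, 0, 0), ((1, 0, 0), (0, 0, 1)))
        v2 = ViewGeometry((700, 700, 0), (0, 0, 0), ((0, 1, 0), (0, 0, 1)))
        with pytest.raises(ValueError, match="orthogonal"):
            ProjectionGeometry(views=(v, v2))


class TestPositioningDelta:
    def test_zero_when_poses_agree(self):
        p = RigidPose((1, 2, 3), (0.5, 0, 0))
        d = positioning_delta(p, p)
        assert d.shift_mm == (0, 0, 0) and d.rotation_deg == (0, 0, 0)

    def test_offset_subtraction_example(self):
        # ct 1.0 mm, sct 1.8 mm, static offset 0.3 mm -> 0.5 mm difference
        ct = RigidPose((1.0, 0, 0))
        sct = RigidPose((1.8, 0, 0))
        off = RigidPose((0.3, 0, 0))
        d = positioning_delta(ct, sct, off)
        assert d.shift_mm[0] == pytest.approx(0.5, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(42)
        a = RigidPose(tuple(rng.uniform(-5, 5, 3)), tuple(rng.uniform(-3, 3, 3)))
        b = RigidPose(tuple(rng.uniform(-5, 5, 3)), tuple(rng.uniform(-3, 3, 3)))
        off = RigidPose(tuple(rng.uniform(-1, 1, 3)), tuple(rng.uniform(-1, 1, 3)))
        neg_off = RigidPose(tuple(-np.array(off.translations_mm)), tuple(-np.array(off.rotations_deg)))
        fwd = positioning_delta(a, b, off)
        rev = positioning_delta(b, a, neg_off)
        assert np.allclose(fwd.shift_mm, -np.array(rev.shift_mm), atol=1e-12)
        assert np.allclose(fwd.rotation_deg, -np.array(rev.rotation_deg), atol=1e-12)


class TestDRR:
    def test_all_air_volume_projects_to_zero(self, geom):
        air = Volume(np.full((16, 16, 16), -1000.0), (-16, -16, -16), (2, 2, 2))
        with pytest.warns(UserWarning, match="frustum"):
            img = generate_drr(air, geom.views[0])
        assert np.all(img == 0.0)

    def test_water_cube_thickness_with_distant_source(self):
        """With a nearly parallel beam the interior pixels equal cube
        thickness x density."""
        n, sp = 20, 2.0
        origin = -sp * (n - 1) / 2
        cube = Volume(np.zeros((n, n, n)), (origin,) * 3, (sp,) * 3)  # water, 40 mm
        view = ViewGeometry(
            source_position_mm=(0.0, 1e7, 0.0),
            detector_center_mm=(0.0, 0.0, 0.0),
            detector_axes=((1, 0, 0), (0, 0, 1)),
            pixel_spacing_mm=2.0,
            detector_size_px=(32, 32),
        )
        img = generate_drr(cube, view)
        interior = img[12:20, 12:20]
        assert np.all(np.abs(interior - n * sp) / (n * sp) < 0.005)

    def test_doubling_density_doubles_every_pixel(self, small_pair, geom):
        from sctqa.positioning import _attenuation, _project

        att = _attenuation(small_pair.ct, True, None)
        img = _project(att, small_pair.ct, geom.views[0])
        img2 = _project(np.ascontiguousarray(2.0 * att), small_pair.ct, geom.views[0])
        assert np.allclose(img2, 2.0 * img, rtol=1e-12)

    def test_identity_kv_matches_drr(self, small_pair, geom):
        kv = simulate_kv_pair(small_pair.ct, RigidPose.identity(), geom, noise_level=0.0)
        drr0 = generate_drr(small_pair.ct, geom.views[0], bone_weighting=True)
        drr1 = generate_drr(small_pair.ct, geom.views[1], bone_weighting=True)
        assert np.allclose(kv[0], drr0) and np.allclose(kv[1], drr1)

    def test_same_seed_same_images(self, small_pair, geom):
        a = simulate_kv_pair(small_pair.ct, RigidPose((1, 0, 0)), geom, noise_level=0.02, seed=9)
        b = simulate_kv_pair(small_pair.ct, RigidPose((1, 0, 0)), geom, noise_level=0.02, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_lateral_shift_moves_image_by_expected_pixels(self, small_pair, geom):
        """A pure lateral couch shift moves the AP projection along the
        detector u axis by shift / pixel spacing (unit magnification at
        the isocenter plane); verified by the cross-correlation peak."""
        shift = 6.0  # mm -> 3 px at 2 mm pixels
        kv = simulate_kv_pair(small_pair.ct, RigidPose((shift, 0, 0)), geom, noise_level=0.0)
        ref = generate_drr(small_pair.ct, geom.views[0], bone_weighting=True)
        from sctqa.positioning import _fft_shift_estimate

        du, dv = _fft_shift_estimate(ref, kv[0])
        assert du * geom.views[0].pixel_spacing_mm == pytest.approx(shift, abs=0.3)
        assert abs(dv) * geom.views[0].pixel_spacing_mm < 0.3


class TestRegistration:
    def test_2d2d_recovers_planted_pose(self, geom):
        pair = generate_phantom_pair(PhantomSpec(), ErrorMode.none())
        true_pose = RigidPose((2.0, -1.0, 3.0), (1.0, 0.5, -0.5))
        kv = simulate_kv_pair(pair.ct, true_pose, geom, noise_level=0.0)
        res = register_2d2d(kv, pair.ct, geom)
        err = np.abs(res.pose.as_vector() - true_pose.as_vector())
        assert np.all(err[:3] <= 0.2) and np.all(err[3:] <= 0.2)
        assert res.status == "ok"

    def test_spherical_phantom_flags_rotational_degeneracy(self, geom):
        spec = PhantomSpec(
            head_semiaxes_mm=(75.0, 75.0, 75.0),
            bone_landmarks=False,
            sinus_center_mm=(0.0, 0.0, 0.0),
            sinus_half_mm=(8.0, 8.0, 8.0),
            noise_sigma_hu=0.0,
        )
        pair = generate_phantom_pair(spec, ErrorMode.none())
        kv = simulate_kv_pair(pair.ct, RigidPose.identity(), geom, noise_level=0.0)
        res = register_2d2d(kv, pair.ct, geom, rotation_search_deg=3.0, refine_maxiter=(20, 10))
        assert res.multi_optimum

    def test_3d_self_registration_is_identity(self, small_pair):
        res = register_3d_rigid(small_pair.ct, small_pair.ct)
        v = np.abs(res.pose.as_vector())
        assert np.all(v[:3] <= 0.05) and np.all(v[3:] <= 0.05)
        assert res.similarity >= 0.999

    def test_3d_recovers_known_offset(self, small_pair):
        from sctqa.positioning import _resample_under_pose

        true_pose = RigidPose((3.0, -2.0, 1.0), (1.0, -0.8, 0.6))
        center = small_pair.ct.index_to_physical((np.asarray(small_pair.ct.shape) - 1) / 2.0)
        moved = _resample_under_pose(small_pair.ct, true_pose, center)
        res = register_3d_rigid(small_pair.ct, moved)
        err = np.abs(res.pose.as_vector() - true_pose.as_vector())
        assert np.all(err[:3] <= 0.2) and np.all(err[3:] <= 0.2)

    def test_none_sct_registers_near_identity(self, small_pair):
        res = register_3d_rigid(small_pair.sct, small_pair.ct)
        v = np.abs(res.pose.as_vector())
        assert np.all(v[:3] <= 0.1) and np.all(v[3:] <= 0.1)
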