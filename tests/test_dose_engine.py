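"""HU->density calibration, Siddon traversal, and the toy beam model."""

import numpy as np
import pytest

from sctqa.dose import (
    BeamSpec,
    DensityCalibration,
    PlanSpec,
    compute_plan_dose,
    default_plan,
    hu_to_density,
    radiological_path,
)
from sctqa.geometry import StructureMask, Volume


class TestDensityCalibration:
    def test_water_maps_to_unity(self):
        assert hu_to_density(0.0) == 1.0

    def test_clamped_below_range(self):
        cal = DensityCalibration()
        assert hu_to_density(-5000.0, cal) == cal.density[0]

    def test_midpoint_is_mean_of_neighbours(self):
        cal = DensityCalibration(points=((-1000, 0.0), (0, 1.0), (1000, 1.5)))
        assert hu_to_density(500.0, cal) == pytest.approx(1.25)

    def test_requires_water_point_and_monotone_hu(self):
        with pytest.raises(ValueError, match="water"):
            DensityCalibration(points=((-1000, 0.0), (100, 1.1)))
        with pytest.raises(ValueError, match="increasing"):
            DensityCalibration(points=((0, 1.0), (0, 1.0)))


def _fine_step_wepl(density_vol, src, dst, step_mm=0.002):
    """Dense ray-marching oracle: piecewise-constant sampling at a fine step."""
    src, dst = np.asarray(src, float), np.asarray(dst, float)
    n_steps = max(2000, int(np.linalg.norm(dst - src) / step_mm))
    ts = (np.arange(n_steps) + 0.5) / n_steps
    pts = src + ts[:, None] * (dst - src)
    idx = np.round(density_vol.physical_to_index(pts)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(density_vol.shape)), axis=1)
    seg = np.linalg.norm(dst - src) / n_steps
    vals = density_vol.values[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
    return float(vals.sum() * seg)


class TestRadiologicalPath:
    @pytest.fixture
    def water_cube(self):
        return Volume(np.ones((10, 10, 10)), (0, 0, 0), (10, 10, 10), frame_id="w")

    def test_axis_aligned_chord(self, water_cube):
        # 100 mm of unit density water
        assert radiological_path(water_cube, (-50, 45, 45), (200, 45, 45)) == pytest.approx(100.0)

    def test_linear_in_density(self, water_cube):
        half = water_cube.with_values(np.full((10, 10, 10), 0.5))
        assert radiological_path(half, (-50, 45, 45), (200, 45, 45)) == pytest.approx(50.0)

    def test_zero_length_segment(self, water_cube):
        assert radiological_path(water_cube, (45, 45, 45), (45, 45, 45)) == 0.0

    def test_miss_returns_zero(self, water_cube):
        assert radiological_path(water_cube, (-50, -50, -50), (-50, 500, -50)) == 0.0

    def test_oblique_rays_match_fine_step_oracle(self):
        rng = np.random.default_rng(7)
        vol = Volume(rng.uniform(0.2, 2.0, (8, 8, 8)), (-8, -8, -8), (2, 2, 2), frame_id="w")
        for _ in range(20):
            src = rng.uniform(-60, -20, 3)
            dst = rng.uniform(20, 60, 3)
            exact = radiological_path(vol, src, dst)
            approx = _fine_step_wepl(vol, src, dst)
            assert exact == pytest.approx(approx, rel=1e-3)

    def test_density_scaling_scales_wepl_exactly(self):
        rng = np.random.default_rng(8)
        vol = Volume(rng.uniform(0.1, 3.0, (6, 6, 6)), (0, 0, 0), (3, 3, 3), frame_id="w")
        scaled = vol.with_values(vol.values * 1.7)
        src, dst = (-10, 5, 8), (30, 12, 6)
        assert radiological_path(scaled, src, dst) == pytest.approx(
            1.7 * radiological_path(vol, src, dst), rel=1e-12
        )


def _water_phantom(n=64, spacing=2.0):
    origin = -spacing * (n - 1) / 2.0
    values = np.zeros((n, n, n))  # 0 HU = water everywhere
    return Volume(values, (origin, origin, origin), (spacing,) * 3, frame_id="w")


def _central_axis_plan(sad=1000.0):
    beam = BeamSpec(
        source_position_mm=(0.0, sad, 0.0),
        isocenter_mm=(0.0, 0.0, 0.0),
        aperture_radius_mm=20.0,
        penumbra_sigma_mm=3.0,
    )
    return PlanSpec(beams=(beam,), prescription_gy=60.0, mu_eff_per_mm=0.005)


class TestPlanDose:
    def test_central_axis_ratio_matches_closed_form(self):
        """Depth-dose ratio in homogeneous water = attenuation x inverse square."""
        water = _water_phantom()
        plan = _central_axis_plan()
        mask = np.zeros(water.shape, dtype=bool)
        mask[28:36, 28:36, 28:36] = True
        dose, _ = compute_plan_dose(water, plan, ptv=StructureMask("PTV", mask))
        # central axis: x = z = centre index; depths along -y
        c = 31  # voxel index at -1 mm (n=64, spacing 2, centre between 31 and 32)
        axis_pos = water.index_to_physical(
            np.column_stack([np.full(64, c), np.arange(64), np.full(64, c)]).astype(float)
        )
        surface_y = water.index_to_physical([c, 63, c])[1]
        for j1, j2 in [(40, 20), (50, 10), (45, 30)]:
            d1 = dose.values[c, j1, c]
            d2 = dose.values[c, j2, c]
            y1, y2 = axis_pos[j1, 1], axis_pos[j2, 1]
            depth1, depth2 = surface_y - y1 + 1.0, surface_y - y2 + 1.0  # +1: half voxel to surface
            dist1, dist2 = 1000.0 - y1, 1000.0 - y2
            expected = np.exp(-0.005 * (depth1 - depth2)) * (dist2 / dist1) ** 2
            assert d1 / d2 == pytest.approx(expected, rel=5e-3)

    def test_mean_ptv_dose_equals_prescription(self, small_pair, small_plan, small_ct_dose):
        dose, _ = small_ct_dose
        ptv = small_pair.structure("PTV").mask
        assert dose.values[ptv].mean() == pytest.approx(small_plan.prescription_gy, rel=1e-9)

    def test_monitor_units_unchanged_contract(self, small_pair, small_plan, small_ct_dose):
        """Recalculating on an identical image with the CT's factor is
        bit-identical; the factor is never re-derived."""
        dose_ct, mu = small_ct_dose
        again, mu2 = compute_plan_dose(
            small_pair.ct, small_plan, ptv=small_pair.structure("PTV"), mu_factor=mu
        )
        assert mu2 == mu
        assert np.array_equal(again.values, dose_ct.values)

    def test_dose_decreases_with_depth_inside_aperture(self):
        water = _water_phantom()
        plan = _central_axis_plan()
        mask = np.zeros(water.shape, dtype=bool)
        mask[28:36, 28:36, 28:36] = True
        dose, _ = compute_plan_dose(water, plan, ptv=StructureMask("PTV", mask))
        c = 31
        axis = dose.values[c, :, c]  # increasing j = decreasing depth
        assert np.all(np.diff(axis[2:-2]) > 0)

    def test_empty_ptv_without_factor_rejected(self):
        water = _water_phantom(16)
        plan = _central_axis_plan()
        empty = StructureMask("PTV", np.zeros(water.shape, dtype=bool))
        with pytest.raises(ValueError, match="PTV"):
            compute_plan_dose(water, plan, ptv=empty)

    def test_default_plan_geometry(self):
        plan = default_plan((0, 0, 0), 12.0)
        assert len(plan.beams) == 4
        assert plan.beams[0].aperture_radius_mm == 17.0
        srcs = np.array([b.source_position_mm for b in plan.beams])
        assert np.allclose(np.linalg.norm(srcs, axis=1), 1000.0)
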