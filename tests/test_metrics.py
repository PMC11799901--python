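"""Mean error arithmetic and the local gamma analysis vs its oracle."""

import numpy as np
import pytest

from sctqa.geometry import StructureMask, Volume
from sctqa.metrics import GammaCriteria, gamma_bruteforce, gamma_map, mean_error


def vol(values, spacing=(2.0, 2.0, 2.0), frame="f"):
    return Volume(np.asarray(values, dtype=float), (0, 0, 0), spacing, frame_id=frame)


class TestMeanError:
    def test_identical_doses(self):
        d = vol(np.full((3, 3, 3), 2.0))
        mask = StructureMask("s", np.ones((3, 3, 3), dtype=bool))
        assert mean_error(d, d, mask, 60.0) == (0.0, 0.0)

    def test_hand_example(self):
        # eval {2.02, 2.04, 2.00} vs ref 2.00 over 3 voxels at 60 Gy
        ref = vol(np.full((3, 1, 1), 2.0))
        ev = vol(np.array([2.02, 2.04, 2.00]).reshape(3, 1, 1))
        mask = StructureMask("s", np.ones((3, 1, 1), dtype=bool))
        me_gy, me_pct = mean_error(ev, ref, mask, 60.0)
        assert me_gy == pytest.approx(0.02, abs=1e-12)
        assert me_pct == pytest.approx(0.02 / 60.0 * 100.0, abs=1e-9)

    def test_linearity_under_constant_shift(self):
        rng = np.random.default_rng(21)
        ref = vol(rng.uniform(0, 60, (5, 5, 5)))
        ev = vol(rng.uniform(0, 60, (5, 5, 5)))
        mask = StructureMask("s", rng.random((5, 5, 5)) > 0.4)
        base, _ = mean_error(ev, ref, mask, 60.0)
        for c in (-1.5, 0.7, 3.0):
            shifted, _ = mean_error(ev.with_values(ev.values + c), ref, mask, 60.0)
            assert shifted == pytest.approx(base + c, abs=1e-9)

    def test_grid_mismatch_rejected(self):
        a = vol(np.zeros((3, 3, 3)))
        b = Volume(np.zeros((3, 3, 3)), (1, 0, 0), (2, 2, 2), frame_id="f")
        with pytest.raises(ValueError, match="grid"):
            mean_error(a, b, StructureMask("s", np.ones((3, 3, 3), dtype=bool)), 60.0)

    def test_empty_mask_rejected(self):
        d = vol(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            mean_error(d, d, StructureMask("s", np.zeros((3, 3, 3), dtype=bool)), 60.0)


class TestGammaClosedForms:
    def test_identical_doses_gamma_zero(self):
        rng = np.random.default_rng(22)
        ref = vol(rng.uniform(1, 2, (6, 6, 6)))
        gmap, rate = gamma_map(ref, ref.copy())
        assert rate == 100.0
        assert np.nanmax(gmap.values) == 0.0

    def test_uniform_field_half_percent_scaling(self):
        """A 0.5% dose offset on a uniform field gives gamma 0.5 exactly:
        spatial search cannot reduce the dose term of a uniform field."""
        ref = vol(np.full((10, 10, 10), 2.0))
        ev = ref.with_values(ref.values * 1.005)
        gmap, rate = gamma_map(ref, ev)
        assert rate == 100.0
        included = ~np.isnan(gmap.values)
        assert np.all(np.abs(gmap.values[included] - 0.5) <= 1e-9)

    def test_uniform_field_two_percent_scaling_fails(self):
        ref = vol(np.full((8, 8, 8), 2.0))
        ev = ref.with_values(ref.values * 1.02)
        _, rate = gamma_map(ref, ev)
        assert rate == 0.0

    def test_single_voxel_dose_term_only(self):
        # no spatial freedom on a 1-voxel grid: gamma = |dose diff| / 1%
        ref = vol(np.full((1, 1, 1), 1.0))
        g2, _ = gamma_bruteforce(ref, ref.with_values(np.full((1, 1, 1), 1.02)))
        assert g2.values[0, 0, 0] == pytest.approx(2.0)
        g05, _ = gamma_bruteforce(ref, ref.with_values(np.full((1, 1, 1), 1.005)))
        assert g05.values[0, 0, 0] == pytest.approx(0.5)

    def test_all_below_threshold_rejected(self):
        ref = vol(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="threshold"):
            gamma_map(ref, ref)


def _random_pair(rng, n, rel_noise=0.01, spacing=2.0):
    base = rng.uniform(1.0, 2.0, (n, n, n))
    ref = vol(base, spacing=(spacing,) * 3)
    ev = vol(base * (1 + rel_noise * rng.standard_normal((n, n, n))), spacing=(spacing,) * 3)
    return ref, ev


class TestGammaOracle:
    def test_map_equals_bruteforce(self):
        rng = np.random.default_rng(23)
        criteria = GammaCriteria(interp_fraction=0.25)
        for _ in range(3):
            ref, ev = _random_pair(rng, 12)
            gm, pm = gamma_map(ref, ev, criteria)
            gb, pb = gamma_bruteforce(ref, ev, criteria)
            assert pm == pb
            both = ~np.isnan(gm.values)
            below_cap = both & (gb.values < criteria.gamma_cap)
            assert np.max(np.abs(gm.values[below_cap] - gb.values[below_cap])) <= 1e-6

    def test_pass_rate_monotone_in_criteria(self):
        rng = np.random.default_rng(24)
        ref, ev = _random_pair(rng, 10, rel_noise=0.02)
        rates = []
        for dose_pc, dist in [(1.0, 1.0), (2.0, 1.0), (2.0, 2.0), (3.0, 3.0)]:
            _, rate = gamma_map(ref, ev, GammaCriteria(dose_percent=dose_pc, distance_mm=dist, interp_fraction=0.25))
            rates.append(rate)
        assert np.all(np.diff(rates) >= 0)

    def test_finer_lattice_never_increases_gamma(self):
        rng = np.random.default_rng(25)
        ref, ev = _random_pair(rng, 8, rel_noise=0.015)
        coarse, _ = gamma_map(ref, ev, GammaCriteria(interp_fraction=0.5))
        fine, _ = gamma_map(ref, ev, GammaCriteria(interp_fraction=0.25))
        ok = ~np.isnan(coarse.values)
        assert np.all(fine.values[ok] <= coarse.values[ok] + 1e-12)

    def test_gamma_nonnegative_and_capped(self):
        rng = np.random.default_rng(26)
        ref, ev = _random_pair(rng, 10, rel_noise=0.05)
        gmap, _ = gamma_map(ref, ev, GammaCriteria(interp_fraction=0.25))
        vals = gmap.values[~np.isnan(gmap.values)]
        assert np.all(vals >= 0.0) and np.all(vals <= 2.0)
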