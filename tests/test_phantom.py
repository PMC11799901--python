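"""Phantom generation, error modes, cohorts, and bias calibration."""

from dataclasses import replace

import numpy as np
import pytest

from sctqa.dose import compute_dose_at, default_plan
from sctqa.dvh import threshold_structures
from sctqa.phantom import (
    CohortSpec,
    ErrorMode,
    PhantomSpec,
    calibrate_bias,
    generate_cohort,
    generate_phantom_pair,
)


class TestPhantomPair:
    def test_none_mode_without_noise_is_identical(self, small_spec):
        spec = replace(small_spec, noise_sigma_hu=0.0)
        pair = generate_phantom_pair(spec, ErrorMode.none())
        assert np.array_equal(pair.ct.values, pair.sct.values)

    def test_deterministic_for_fixed_seed(self, small_spec):
        a = generate_phantom_pair(small_spec, ErrorMode.metal_artifact())
        b = generate_phantom_pair(small_spec, ErrorMode.metal_artifact())
        assert np.array_equal(a.sct.values, b.sct.values)
        assert np.array_equal(a.ct.values, b.ct.values)

    def test_metal_artifact_support(self, small_spec):
        """sCT-CT differences appear exactly within the artifact support
        (implant sphere plus its streak slab)."""
        spec = replace(small_spec, noise_sigma_hu=0.0)
        mode = ErrorMode.metal_artifact(radius_mm=8.0, amplitude_hu=3000.0)
        pair = generate_phantom_pair(spec, mode)
        diff = pair.sct.values - pair.ct.values
        grid = spec.grid()
        coords = [np.arange(n) * s + o for n, s, o in zip(grid.shape, grid.spacing, grid.origin)]
        x, y, z = np.meshgrid(*coords, indexing="ij")
        pc = spec.ptv_center
        center = (45.0, pc[1], pc[2])
        implant = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= 8.0**2
        slab = np.abs(z - center[2]) <= 8.0
        assert np.all(diff[implant] != 0.0)
        assert np.all(diff[~(implant | slab)] == 0.0)

    def test_ct_is_noise_free_and_sct_noisy_inside_body(self, small_pair):
        body = small_pair.structure("Body").mask
        diff = small_pair.sct.values - small_pair.ct.values
        assert np.all(diff[~body] == 0.0)
        assert np.std(diff[body]) == pytest.approx(20.0, rel=0.05)

    def test_ptv_outside_brain_rejected(self, small_spec):
        bad = replace(small_spec, ptv_center_mm=(0.0, 80.0, 0.0))
        with pytest.raises(ValueError, match="PTV"):
            generate_phantom_pair(bad, ErrorMode.none())

    def test_threshold_recovers_planted_masks(self, phantom_pair):
        brain, skull = threshold_structures(phantom_pair.ct)
        assert np.array_equal(brain.mask, phantom_pair.structure("Brain").mask)
        assert np.array_equal(skull.mask, phantom_pair.structure("Skull").mask)

    def test_bulk_density_quantises_to_classes(self, small_spec):
        spec = replace(small_spec, noise_sigma_hu=0.0)
        pair = generate_phantom_pair(spec, ErrorMode.bulk_density())
        assert set(np.unique(pair.sct.values)) <= {-1000.0, 0.0, 700.0}

    def test_sinus_misprediction_fills_sinus_only(self, small_spec):
        spec = replace(small_spec, noise_sigma_hu=0.0)
        pair = generate_phantom_pair(spec, ErrorMode.sinus_misprediction(30.0))
        diff = pair.sct.values - pair.ct.values
        sinus = pair.structure("Sinus").mask
        assert np.all(diff[sinus] == 1030.0)  # air -1000 -> tissue 30
        assert np.all(diff[~sinus] == 0.0)


class TestCohort:
    def test_all_none_cohort_has_no_failures(self, small_spec):
        pairs, truth = generate_cohort(CohortSpec(n_patients=3, base_spec=small_spec))
        assert len(pairs) == 3
        assert truth["planted_failure"].sum() == 0

    def test_planted_failures_listed_in_truth_table(self, small_spec):
        cohort = CohortSpec(
            n_patients=20,
            mode_assignment=(
                (7, ErrorMode.metal_artifact(), {}),
                (14, ErrorMode.metal_artifact(), {}),
            ),
            base_spec=small_spec,
        )
        _, truth = generate_cohort(cohort)
        assert truth["planted_failure"].sum() == 2
        assert sorted(truth[truth["planted_failure"]]["patient_id"]) == [7, 14]

    def test_same_master_seed_reproduces_cohort(self, small_spec):
        cohort = CohortSpec(n_patients=3, base_spec=small_spec, master_seed=5)
        pairs_a, truth_a = generate_cohort(cohort)
        pairs_b, truth_b = generate_cohort(cohort)
        assert truth_a.equals(truth_b)
        for a, b in zip(pairs_a, pairs_b):
            assert np.array_equal(a.sct.values, b.sct.values)

    def test_duplicate_patient_ids_rejected(self, small_spec):
        with pytest.raises(ValueError, match="unique"):
            CohortSpec(
                n_patients=5,
                mode_assignment=((1, ErrorMode.none(), {}), (1, ErrorMode.none(), {})),
                base_spec=small_spec,
            )


class TestNoiseAveragesOutOverPTV:
    def test_me_ptv_small_for_faithful_generator(self, default_spec):
        """Across seeds, noise-only sCTs stay within 0.3% mean PTV dose error."""
        plan = default_plan(default_spec.ptv_center, default_spec.ptv_radius_mm)
        ref_pair = generate_phantom_pair(replace(default_spec, noise_sigma_hu=0.0), ErrorMode.none())
        ptv_pts = ref_pair.ct.index_to_physical(
            np.argwhere(ref_pair.structure("PTV").mask).astype(float)
        )
        ref_raw = compute_dose_at(ref_pair.ct, plan, points_mm=ptv_pts)
        mu = plan.prescription_gy / ref_raw.mean()
        for seed in range(10):
            pair = generate_phantom_pair(replace(default_spec, seed=seed), ErrorMode.none())
            raw = compute_dose_at(pair.sct, plan, points_mm=ptv_pts)
            me_pct = 100.0 * mu * (raw - ref_raw).mean() / plan.prescription_gy
            assert abs(me_pct) < 0.3


class TestCalibrateBias:
    def test_zero_target_is_zero_shift(self):
        assert calibrate_bias(0.0) == 0.0

    def test_negative_target_needs_positive_shift(self, default_spec):
        dhu = calibrate_bias(-1.0, spec=default_spec)
        assert dhu > 0

    def test_magnitude_monotonic_in_target(self, default_spec):
        d1 = calibrate_bias(-0.5, spec=default_spec)
        d2 = calibrate_bias(-1.5, spec=default_spec)
        assert abs(d2) > abs(d1) > 0

    def test_unreachable_target_reports_bracket(self, default_spec):
        with pytest.raises(ValueError, match="not bracketed"):
            calibrate_bias(-50.0, spec=default_spec)
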