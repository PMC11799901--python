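"""Synthetic paired CT/sCT head phantoms with plantable sCT error modes.

Clinical MR-only cohorts are not public, so the pipeline is exercised on
digital head phantoms: an ellipsoidal head with a skull shell (HU >= 100),
brain tissue (HU in [-100, 100]), an air sinus cavity, and a spherical PTV
placed either near the sinus or deep in the brain.  The paired "synthetic
CT" is the same anatomy corrupted by a chosen error mode:

* ``NONE`` - a faithful generator; only Gaussian HU noise inside the body.
* ``SYSTEMATIC_BIAS`` - soft-tissue HU shifted by a constant, emulating a
  generator with a systematic density bias (calibrated with
  :func:`calibrate_bias` to a target mean-dose error, e.g. -1%).
* ``SINUS_MISPREDICTION`` - the air sinus filled with tissue-like HU, the
  classic failure of sCT generators in heterogeneous regions.
* ``METAL_ARTIFACT`` - a high-HU implant sphere with radial streaks, the
  "true failure" patient every QA procedure should catch.
* ``BULK_DENSITY`` - HU quantised to a few tissue classes, emulating a
  bulk-density-assignment generator.

Ground truth (which pairs are planted failures) travels with each phantom so
classification results can be audited against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from sctqa.geometry import StructureMask, Volume

__all__ = [
    "PhantomSpec",
    "ErrorMode",
    "CohortSpec",
    "GroundTruth",
    "PhantomPair",
    "generate_phantom_pair",
    "generate_cohort",
    "calibrate_bias",
]


@dataclass(frozen=True)
class ErrorMode:
    """Declarative description of the planted sCT failure."""

    kind: str = "NONE"
    bias_hu: float = 0.0
    sinus_fill_hu: float = 0.0
    artifact_center_mm: tuple[float, float, float] | None = None
    artifact_radius_mm: float = 8.0
    artifact_amplitude_hu: float = 3000.0
    streak_amplitude_hu: float = 300.0
    bulk_class_hu: tuple[float, float, float] = (-1000.0, 0.0, 700.0)
    bulk_thresholds: tuple[float, float] = (-200.0, 150.0)
    bulk_soft_bias_hu: float = 0.0

    KINDS = ("NONE", "SYSTEMATIC_BIAS", "SINUS_MISPREDICTION", "METAL_ARTIFACT", "BULK_DENSITY")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown error mode {self.kind!r}")

    # convenience constructors -------------------------------------------
    @classmethod
    def none(cls) -> "ErrorMode":
        return cls(kind="NONE")

    @classmethod
    def systematic_bias(cls, bias_hu: float) -> "ErrorMode":
        return cls(kind="SYSTEMATIC_BIAS", bias_hu=bias_hu)

    @classmethod
    def sinus_misprediction(cls, fill_hu: float = 30.0) -> "ErrorMode":
        return cls(kind="SINUS_MISPREDICTION", sinus_fill_hu=fill_hu)

    @classmethod
    def metal_artifact(
        cls,
        center_mm: tuple[float, float, float] | None = None,
        radius_mm: float = 8.0,
        amplitude_hu: float = 3000.0,
    ) -> "ErrorMode":
        return cls(
            kind="METAL_ARTIFACT",
            artifact_center_mm=center_mm,
            artifact_radius_mm=radius_mm,
            artifact_amplitude_hu=amplitude_hu,
        )

    @classmethod
    def bulk_density(cls, soft_bias_hu: float = 0.0) -> "ErrorMode":
        return cls(kind="BULK_DENSITY", bulk_soft_bias_hu=soft_bias_hu)

    @property
    def is_planted_failure(self) -> bool:
        """Whether the mode is a ground-truth QA failure (metal implant)."""
        return self.kind == "METAL_ARTIFACT"


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of one synthetic head.

    HU defaults keep the thresholding contract intact on the noise-free CT:
    brain HU inside [-100, 100], skull HU >= 100, so HU windowing recovers
    the planted compartments exactly.  Coordinates are mm relative to the
    grid centre (the head centre).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    head_semiaxes_mm: tuple[float, float, float] = (70.0, 85.0, 80.0)
    skull_thickness_mm: float = 6.0
    hu_brain: float = 30.0
    hu_skull: float = 800.0
    hu_air: float = -1000.0
    sinus_center_mm: tuple[float, float, float] = (0.0, 48.0, -25.0)
    sinus_half_mm: tuple[float, float, float] = (12.0, 10.0, 9.0)
    ptv_placement: str = "near_sinus"  # or "deep"
    ptv_radius_mm: float = 12.0
    ptv_center_mm: tuple[float, float, float] | None = None
    bone_landmarks: bool = True
    noise_sigma_hu: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-100.0 <= self.hu_brain <= 100.0):
            raise ValueError("hu_brain must lie in [-100, 100] (thresholding contract)")
        if self.hu_skull < 100.0:
            raise ValueError("hu_skull must be >= 100 (thresholding contract)")
        if self.ptv_placement not in ("near_sinus", "deep"):
            raise ValueError("ptv_placement must be 'near_sinus' or 'deep'")

    @property
    def ptv_center(self) -> tuple[float, float, float]:
        if self.ptv_center_mm is not None:
            return self.ptv_center_mm
        return (0.0, 22.0, -22.0) if self.ptv_placement == "near_sinus" else (0.0, -10.0, 10.0)

    def grid(self, frame_id: str = "phantom") -> Volume:
        """An empty (air) Volume centred on the head centre."""
        shape = self.grid_shape
        spacing = np.asarray(self.spacing_mm, dtype=float)
        origin = -spacing * (np.asarray(shape) - 1) / 2.0
        return Volume(np.full(shape, self.hu_air), origin, spacing, frame_id=frame_id)


@dataclass
class GroundTruth:
    """Audit record for one phantom pair."""

    patient_id: int
    mode_kind: str
    planted_failure: bool
    seed: int
    noise_sigma_hu: float
    ptv_placement: str


@dataclass
class PhantomPair:
    patient_id: int
    ct: Volume
    sct: Volume
    structures: list[StructureMask]
    truth: GroundTruth

    def structure(self, name: str) -> StructureMask:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort: per-patient error modes and spec overrides."""

    n_patients: int
    mode_assignment: tuple[tuple[int, ErrorMode, dict], ...] = ()
    base_spec: PhantomSpec = field(default_factory=PhantomSpec)
    master_seed: int = 0

    def __post_init__(self) -> None:
        ids = [pid for pid, _, _ in self.mode_assignment]
        if len(ids) != len(set(ids)):
            raise ValueError("patient_ids in mode_assignment must be unique")

    def patients(self) -> list[tuple[int, ErrorMode, dict]]:
        """Patient list 1..n with NONE for unassigned patients."""
        assigned = {pid: (mode, overrides) for pid, mode, overrides in self.mode_assignment}
        out = []
        for pid in range(1, self.n_patients + 1):
            mode, overrides = assigned.get(pid, (ErrorMode.none(), {}))
            out.append((pid, mode, overrides))
        return out


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _phantom_geometry(spec: PhantomSpec):
    """Compartment masks of the head phantom on its grid."""
    grid = spec.grid()
    shape = grid.shape
    coords = [np.arange(n) * s + o for n, s, o in zip(shape, grid.spacing, grid.origin)]
    x, y, z = np.meshgrid(*coords, indexing="ij")

    a = np.asarray(spec.head_semiaxes_mm, dtype=float)
    inner = a - spec.skull_thickness_mm
    head = (x / a[0]) ** 2 + (y / a[1]) ** 2 + (z / a[2]) ** 2 <= 1.0
    brain_region = (x / inner[0]) ** 2 + (y / inner[1]) ** 2 + (z / inner[2]) ** 2 <= 1.0
    skull = head & ~brain_region

    # bony landmarks: a smooth ellipsoidal shell is nearly rotation-invariant
    # in projection, which would make bone-driven 2D/2D registration
    # degenerate; a septum, a skull-base plate with a foramen, and two
    # asymmetric mastoid-like studs anchor all three rotation axes.
    landmarks = np.zeros(grid.shape, dtype=bool)
    if spec.bone_landmarks:
        sc0 = np.asarray(spec.sinus_center_mm)
        sh0 = np.asarray(spec.sinus_half_mm)
        septum = (
            (np.abs(x - sc0[0]) <= 1.5)
            & (np.abs(y - sc0[1]) <= sh0[1])
            & (np.abs(z - sc0[2]) <= sh0[2] + 6.0)
        )
        plate = (z >= -42.0) & (z <= -36.0) & ((x / (0.8 * inner[0])) ** 2 + (y / (0.8 * inner[1])) ** 2 <= 1.0)
        foramen = (x**2 + (y - 10.0) ** 2 <= 10.0**2)
        plate &= ~foramen
        stud_r = (x - 50.0) ** 2 + (y + 25.0) ** 2 + (z + 30.0) ** 2 <= 6.0**2
        stud_l = (x + 48.0) ** 2 + (y + 28.0) ** 2 + (z + 32.0) ** 2 <= 9.0**2
        landmarks = (septum | plate | stud_r | stud_l) & brain_region
    skull = skull | landmarks

    sc = np.asarray(spec.sinus_center_mm)
    sh = np.asarray(spec.sinus_half_mm)
    sinus = (
        (np.abs(x - sc[0]) <= sh[0])
        & (np.abs(y - sc[1]) <= sh[1])
        & (np.abs(z - sc[2]) <= sh[2])
        & brain_region
        & ~landmarks
    )
    brain = brain_region & ~sinus & ~landmarks

    pc = np.asarray(spec.ptv_center)
    ptv = (x - pc[0]) ** 2 + (y - pc[1]) ** 2 + (z - pc[2]) ** 2 <= spec.ptv_radius_mm**2
    return grid, (x, y, z), head, skull, brain, sinus, ptv


def generate_phantom_pair(
    spec: PhantomSpec,
    mode: ErrorMode | None = None,
    patient_id: int = 0,
    frame_id: str | None = None,
) -> PhantomPair:
    """Build one paired (CT, sCT) head phantom with planted structures.

    The CT is noise-free; the sCT is the CT plus the mode-specific
    perturbation plus Gaussian HU noise (``spec.noise_sigma_hu``) inside the
    body.  Deterministic for a fixed ``spec.seed``.  Rejects a PTV that is
    not entirely inside the brain compartment.
    """
    mode = mode or ErrorMode.none()
    frame = frame_id or f"phantom-{patient_id}"
    grid, (x, y, z), head, skull, brain, sinus, ptv = _phantom_geometry(spec)

    if not np.all(brain[ptv]):
        raise ValueError("PTV is not entirely inside the brain compartment")

    ct_values = np.full(grid.shape, spec.hu_air, dtype=float)
    ct_values[brain] = spec.hu_brain
    ct_values[skull] = spec.hu_skull
    ct_values[sinus] = spec.hu_air

    sct_values = ct_values.copy()
    soft_tissue = brain  # the [-100, 100] HU compartment
    if mode.kind == "SYSTEMATIC_BIAS":
        sct_values[soft_tissue] += mode.bias_hu
    elif mode.kind == "SINUS_MISPREDICTION":
        sct_values[sinus] = mode.sinus_fill_hu
    elif mode.kind == "METAL_ARTIFACT":
        center = mode.artifact_center_mm
        if center is None:
            pc = spec.ptv_center
            center = (45.0, pc[1], pc[2])  # lateral to the PTV, on a beam path
        r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
        implant = r2 <= mode.artifact_radius_mm**2
        sct_values[implant] = mode.artifact_amplitude_hu
        # radial streaks in the implant slab, decaying away from the implant
        slab = np.abs(z - center[2]) <= mode.artifact_radius_mm
        r = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2)
        theta = np.arctan2(y - center[1], x - center[0])
        streaks = (
            mode.streak_amplitude_hu
            * np.cos(8.0 * theta)
            * np.exp(-np.maximum(r - mode.artifact_radius_mm, 0.0) / 30.0)
        )
        affected = slab & head & ~implant
        sct_values[affected] += streaks[affected]
    elif mode.kind == "BULK_DENSITY":
        lo, hi = mode.bulk_thresholds
        c_air, c_soft, c_bone = mode.bulk_class_hu
        quantised = np.where(
            sct_values < lo, c_air, np.where(sct_values < hi, c_soft + mode.bulk_soft_bias_hu, c_bone)
        )
        sct_values = quantised.astype(float)

    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sigma_hu, size=grid.shape)
        sct_values = sct_values + np.where(head, noise, 0.0)

    ct = Volume(ct_values, grid.origin, grid.spacing, grid.axes, frame)
    sct = Volume(sct_values, grid.origin, grid.spacing, grid.axes, frame)
    structures = [
        StructureMask("PTV", ptv, source="synthetic"),
        StructureMask("Brain", brain, source="synthetic"),
        StructureMask("Skull", skull, source="synthetic"),
        StructureMask("Body", head, source="synthetic"),
        StructureMask("Sinus", sinus, source="synthetic"),
    ]
    truth = GroundTruth(
        patient_id=patient_id,
        mode_kind=mode.kind,
        planted_failure=mode.is_planted_failure,
        seed=spec.seed,
        noise_sigma_hu=spec.noise_sigma_hu,
        ptv_placement=spec.ptv_placement,
    )
    return PhantomPair(patient_id, ct, sct, structures, truth)


def _patient_seed(master_seed: int, patient_id: int) -> int:
    """Deterministic per-patient seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(patient_id)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(cohort: CohortSpec) -> tuple[list[PhantomPair], pd.DataFrame]:
    """Generate all phantom pairs of a cohort plus the ground-truth table.

    Per-patient seeds are derived deterministically from ``master_seed`` and
    the patient id, and recorded in the truth table for auditability.
    """
    pairs = []
    rows = []
    for pid, mode, overrides in cohort.patients():
        seed = _patient_seed(cohort.master_seed, pid)
        spec = replace(cohort.base_spec, seed=seed, **overrides)
        pair = generate_phantom_pair(spec, mode, patient_id=pid)
        pairs.append(pair)
        rows.append(
            {
                "patient_id": pid,
                "mode": mode.kind,
                "planted_failure": mode.is_planted_failure,
                "seed": seed,
                "noise_sigma_hu": spec.noise_sigma_hu,
                "ptv_placement": spec.ptv_placement,
            }
        )
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dose-targeted bias calibration
# ---------------------------------------------------------------------------

def calibrate_bias(
    target_me_percent: float,
    plan=None,
    spec: PhantomSpec | None = None,
    mode_kind: str = "SYSTEMATIC_BIAS",
    tol_pp: float = 0.05,
    bracket_hu: tuple[float, float] = (-300.0, 300.0),
) -> float:
    """Soft-tissue HU shift whose planted phantom yields a target PTV mean
    dose error (in % of prescription) against its CT.

    Uses bisection on the HU shift; denser soft tissue attenuates more, so
    the mean PTV dose error decreases monotonically with the shift and a
    negative target maps to a positive shift.  ``mode_kind`` selects whether
    the shift is applied as a plain soft-tissue bias or as the soft-class
    offset of the bulk-density mode.  Raises if the target is unreachable
    inside ``bracket_hu``.
    """
    from sctqa.dose import DensityCalibration, compute_dose_at, default_plan

    if target_me_percent == 0.0:
        return 0.0
    spec = replace(spec or PhantomSpec(), noise_sigma_hu=0.0)
    if plan is None:
        plan = default_plan(spec.ptv_center, spec.ptv_radius_mm)
    cal = DensityCalibration()

    def mode_for(dhu: float) -> ErrorMode:
        if mode_kind == "BULK_DENSITY":
            return ErrorMode.bulk_density(soft_bias_hu=dhu)
        return ErrorMode.systematic_bias(dhu)

    ref_pair = generate_phantom_pair(spec, ErrorMode.none())
    ptv_idx = np.argwhere(ref_pair.structure("PTV").mask).astype(float)
    ptv_points = ref_pair.ct.index_to_physical(ptv_idx)
    ref_raw = compute_dose_at(ref_pair.ct, plan, cal, ptv_points)
    mu_factor = plan.prescription_gy / float(ref_raw.mean())

    def me_percent(dhu: float) -> float:
        pair = generate_phantom_pair(spec, mode_for(dhu))
        raw = compute_dose_at(pair.sct, plan, cal, ptv_points)
        me_gy = float((raw - ref_raw).mean()) * mu_factor
        return 100.0 * me_gy / plan.prescription_gy

    lo, hi = bracket_hu
    f_lo = me_percent(lo) - target_me_percent
    f_hi = me_percent(hi) - target_me_percent
    if f_lo * f_hi > 0:
        raise ValueError(
            f"target {target_me_percent}% not bracketed by dHU in [{lo}, {hi}]: "
            f"ME({lo})={f_lo + target_me_percent:.3f}%, ME({hi})={f_hi + target_me_percent:.3f}%"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = me_percent(mid) - target_me_percent
        if abs(f_mid) <= tol_pp or (hi - lo) < 0.25:
            return mid
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)
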