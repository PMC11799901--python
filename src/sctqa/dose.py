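"""Deterministic toy photon dose engine.

The engine exists so that the PSQA metrics have two dose grids to compare:
it is a primary-photon attenuation model (HU -> relative electron density,
Siddon radiological depth, exponential attenuation, inverse-square fall-off,
Gaussian beam penumbra) with *no* scatter or electron transport.  It is an
explicit, documented departure from a clinical treatment planning system;
what matters for QA purposes is that it is density-sensitive, deterministic,
and recalculates with "monitor units unchanged": the normalisation factor is
computed once on the reference CT and reused verbatim on every sCT, so HU
errors in the sCT propagate into dose differences exactly as they would in a
clinical recalculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sctqa._siddon import wepl_segment, wepl_to_points
from sctqa.geometry import StructureMask, Volume

__all__ = [
    "DensityCalibration",
    "BeamSpec",
    "PlanSpec",
    "hu_to_density",
    "radiological_path",
    "compute_dose_at",
    "compute_plan_dose",
    "default_plan",
]

#: lateral profile value below which a beam's contribution is treated as zero
_LATERAL_CUTOFF = 1e-6


@dataclass(frozen=True)
class DensityCalibration:
    """Piecewise-linear HU -> relative (electron) density curve.

    Clamped outside the calibrated range.  Must contain the water point
    ``(0 HU, 1.0)`` exactly and be strictly increasing in HU.
    """

    points: tuple[tuple[float, float], ...] = (
        (-1000.0, 0.001),
        (-100.0, 0.93),
        (0.0, 1.0),
        (100.0, 1.07),
        (1000.0, 1.55),
        (3000.0, 2.50),
    )

    def __post_init__(self) -> None:
        hu = np.array([p[0] for p in self.points])
        rho = np.array([p[1] for p in self.points])
        if np.any(np.diff(hu) <= 0):
            raise ValueError("calibration HU values must be strictly increasing")
        if np.any(rho < 0):
            raise ValueError("calibration densities must be non-negative")
        if not np.any((hu == 0.0) & (rho == 1.0)):
            raise ValueError("calibration must contain the water point (0 HU, 1.0)")

    @property
    def hu(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def density(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class BeamSpec:
    """One divergent circular beam.

    ``aperture_radius_mm`` is the field radius at the isocenter plane;
    ``penumbra_sigma_mm`` the Gaussian lateral rolloff beyond the aperture;
    ``weight`` a unitless fluence scale.
    """

    source_position_mm: tuple[float, float, float]
    isocenter_mm: tuple[float, float, float]
    aperture_radius_mm: float
    weight: float = 1.0
    penumbra_sigma_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.aperture_radius_mm <= 0:
            raise ValueError("aperture_radius_mm must be > 0")
        if np.allclose(self.source_position_mm, self.isocenter_mm):
            raise ValueError("source must differ from isocenter")


@dataclass(frozen=True)
class PlanSpec:
    """A fixed multi-beam plan: prescription, beams, effective attenuation.

    ``mu_eff_per_mm`` is the effective linear attenuation coefficient of the
    primary fluence in water (default 0.005 /mm, a textbook megavoltage
    magnitude).  The normalisation rule is always "mean PTV dose on the
    reference image equals ``prescription_gy``".
    """

    beams: tuple[BeamSpec, ...]
    prescription_gy: float = 60.0
    mu_eff_per_mm: float = 0.005

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription_gy must be > 0")
        if self.mu_eff_per_mm <= 0:
            raise ValueError("mu_eff_per_mm must be > 0")
        if not self.beams:
            raise ValueError("plan needs at least one beam")


def default_plan(
    ptv_center_mm: tuple[float, float, float],
    ptv_radius_mm: float,
    prescription_gy: float = 60.0,
    sad_mm: float = 1000.0,
    n_beams: int = 4,
) -> PlanSpec:
    """Coplanar beams at equal gantry angles aimed at the PTV centroid.

    Default: 4 beams at 0/90/180/270 degrees in the axial (x, y) plane,
    aperture = PTV radius + 5 mm margin.
    """
    c = np.asarray(ptv_center_mm, dtype=float)
    beams = []
    for angle in np.linspace(0.0, 2 * np.pi, n_beams, endpoint=False):
        direction = np.array([np.sin(angle), np.cos(angle), 0.0])
        src = c + sad_mm * direction
        beams.append(
            BeamSpec(
                source_position_mm=tuple(src),
                isocenter_mm=tuple(c),
                aperture_radius_mm=ptv_radius_mm + 5.0,
            )
        )
    return PlanSpec(beams=tuple(beams), prescription_gy=prescription_gy)


def hu_to_density(hu: np.ndarray | float, cal: DensityCalibration | None = None) -> np.ndarray | float:
    """Piecewise-linear interpolation of the calibration, clamped at the ends."""
    if cal is None:
        cal = DensityCalibration()
    out = np.interp(hu, cal.hu, cal.density)
    return float(out) if np.isscalar(hu) else out


def radiological_path(density_volume: Volume, src_mm, dst_mm) -> float:
    """Water-equivalent path length (mm) of the segment src -> dst.

    ``density_volume`` holds relative density (use :func:`hu_to_density`
    first for HU images).  Exact voxel-boundary Siddon traversal: WEPL is
    the sum over traversed voxels of geometric chord length x density.
    A zero-length segment or one that misses the grid returns 0.
    """
    vol = density_volume
    src_local = vol.axes.T @ (np.asarray(src_mm, dtype=float) - vol.origin)
    dst_local = vol.axes.T @ (np.asarray(dst_mm, dtype=float) - vol.origin)
    return float(
        wepl_segment(
            np.ascontiguousarray(vol.values, dtype=np.float64),
            float(vol.spacing[0]), float(vol.spacing[1]), float(vol.spacing[2]),
            src_local[0], src_local[1], src_local[2],
            dst_local[0], dst_local[1], dst_local[2],
        )
    )


def _beam_dose(
    density: np.ndarray,
    volume: Volume,
    positions: np.ndarray,
    beam: BeamSpec,
    mu_eff: float,
) -> np.ndarray:
    """Raw dose array for one beam on the image grid (vectorised geometry,
    Siddon depths only where the lateral profile is non-negligible)."""
    src = np.asarray(beam.source_position_mm, dtype=float)
    iso = np.asarray(beam.isocenter_mm, dtype=float)
    axis = iso - src
    sad = float(np.linalg.norm(axis))
    axis /= sad

    rel = positions - src
    along = rel @ axis
    radial = rel - np.outer(along, axis)
    r = np.linalg.norm(radial, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_iso = np.where(along > 1e-6, r * sad / along, np.inf)

    excess = np.maximum(r_iso - beam.aperture_radius_mm, 0.0)
    lateral = np.exp(-0.5 * (excess / beam.penumbra_sigma_mm) ** 2)
    lateral[along <= 1e-6] = 0.0

    dose = np.zeros(positions.shape[0])
    active = lateral > _LATERAL_CUTOFF
    if not active.any():
        return dose
    src_local = volume.axes.T @ (src - volume.origin)
    targets_local = (positions[active] - volume.origin) @ volume.axes
    wepl = wepl_to_points(
        density,
        float(volume.spacing[0]), float(volume.spacing[1]), float(volume.spacing[2]),
        np.ascontiguousarray(src_local),
        np.ascontiguousarray(targets_local),
    )
    dist2 = np.sum(rel[active] ** 2, axis=1)
    dose[active] = beam.weight * np.exp(-mu_eff * wepl) * lateral[active] * (sad**2 / dist2)
    return dose


def compute_dose_at(
    image: Volume,
    plan: PlanSpec,
    cal: DensityCalibration | None = None,
    points_mm: np.ndarray | None = None,
) -> np.ndarray:
    """Raw (unnormalised) dose at arbitrary physical points.

    Fast path for callers that only need dose in a small region (e.g. the
    PTV mean during bias calibration); shares the exact beam model of
    :func:`compute_plan_dose`.
    """
    if cal is None:
        cal = DensityCalibration()
    density = np.ascontiguousarray(hu_to_density(image.values, cal), dtype=np.float64)
    pts = np.asarray(points_mm, dtype=float).reshape(-1, 3)
    raw = np.zeros(pts.shape[0])
    for beam in plan.beams:
        raw += _beam_dose(density, image, pts, beam, plan.mu_eff_per_mm)
    return raw


def compute_plan_dose(
    image: Volume,
    plan: PlanSpec,
    cal: DensityCalibration | None = None,
    ptv: StructureMask | None = None,
    mu_factor: float | None = None,
) -> tuple[Volume, float]:
    """Compute the plan dose on an HU image; returns ``(dose, mu_factor)``.

    Raw dose at voxel v is
    ``sum_b w_b * exp(-mu_eff * WEPL_b(v)) * lateral_b(v) * (SAD/|v-src|)^2``.

    When ``mu_factor`` is None it is chosen so the mean raw PTV dose scales
    to the prescription ("monitor units"); pass the factor obtained on the
    reference CT when recalculating on an sCT to honour the
    monitor-units-unchanged contract.  The function is pure: identical
    inputs give identical outputs.
    """
    if cal is None:
        cal = DensityCalibration()
    if mu_factor is None and (ptv is None or ptv.is_empty()):
        raise ValueError("a non-empty PTV is required to derive the normalisation factor")

    density = np.ascontiguousarray(hu_to_density(image.values, cal), dtype=np.float64)
    nx, ny, nz = image.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    positions = image.index_to_physical(idx)

    raw = np.zeros(positions.shape[0])
    for beam in plan.beams:
        raw += _beam_dose(density, image, positions, beam, plan.mu_eff_per_mm)
    raw = raw.reshape(image.shape)

    if mu_factor is None:
        mean_ptv = float(raw[ptv.mask].mean())
        if mean_ptv <= 0:
            raise ValueError("mean raw PTV dose is zero; beams miss the PTV")
        mu_factor = plan.prescription_gy / mean_ptv
    return image.with_values(raw * mu_factor), mu_factor
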