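"""Voxel-wise mean error and 3D local gamma analysis.

The mean error (ME) inside a structure is the mean signed voxel-wise dose
difference, evaluated minus reference, in Gy and in % of the prescription.

The gamma index combines a local dose-difference criterion (delta, % of the
reference dose at each voxel) with a distance-to-agreement criterion
(Delta, mm): for every reference voxel above the low-dose threshold,

    gamma(r) = min over evaluated positions e of
               sqrt(|e - r|^2 / Delta^2
                    + (D_eval(e) - D_ref(r))^2 / (delta/100 * D_ref(r))^2)

with the evaluated dose sampled by trilinear interpolation on an offset
lattice of step ``interp_fraction * Delta`` out to radius
``gamma_cap * Delta``.  A voxel passes when gamma <= 1; capped voxels count
as failures.  :func:`gamma_map` prunes the search by visiting lattice
offsets in order of increasing distance (a voxel is final once its current
gamma is below the purely spatial term of every remaining offset), which is
exact: :func:`gamma_bruteforce` evaluates the identical lattice
exhaustively and is the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from sctqa.geometry import StructureMask, Volume

__all__ = ["GammaCriteria", "MetricReport", "mean_error", "gamma_map", "gamma_bruteforce"]


@dataclass(frozen=True)
class GammaCriteria:
    """Criteria of the 3D local gamma analysis.

    Defaults are the 1%/1 mm local analysis with a 20% low-dose threshold:
    voxels below ``threshold_fraction`` of the maximum reference dose are
    excluded both from scoring and from the local denominator.
    """

    dose_percent: float = 1.0
    distance_mm: float = 1.0
    threshold_fraction: float = 0.20
    gamma_cap: float = 2.0
    interp_fraction: float = 0.1

    def __post_init__(self) -> None:
        if min(self.dose_percent, self.distance_mm, self.interp_fraction) <= 0:
            raise ValueError("criteria must be positive")
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.gamma_cap < 1.0:
            raise ValueError("gamma_cap must be >= 1")


@dataclass
class MetricReport:
    """Per-patient, per-reference bundle of PSQA metrics."""

    patient_id: int
    reference_label: str
    me_gy: dict[str, float] = field(default_factory=dict)  # per structure
    me_percent: dict[str, float] = field(default_factory=dict)
    delta_dx_percent: dict[str, float] = field(default_factory=dict)  # per DVH metric (PTV)
    gamma_pass_rate: float | None = None

    def rows(self) -> list[dict]:
        out = []
        for struct, gy in self.me_gy.items():
            out.append(
                {
                    "patient_id": self.patient_id,
                    "reference": self.reference_label,
                    "metric": f"ME_{struct}",
                    "value_gy": gy,
                    "value_percent": self.me_percent[struct],
                }
            )
        for name, pct in self.delta_dx_percent.items():
            out.append(
                {
                    "patient_id": self.patient_id,
                    "reference": self.reference_label,
                    "metric": f"Delta{name}_PTV",
                    "value_gy": np.nan,
                    "value_percent": pct,
                }
            )
        if self.gamma_pass_rate is not None:
            out.append(
                {
                    "patient_id": self.patient_id,
                    "reference": self.reference_label,
                    "metric": "GammaPassRate",
                    "value_gy": np.nan,
                    "value_percent": self.gamma_pass_rate,
                }
            )
        return out


def mean_error(
    eval_dose: Volume, ref_dose: Volume, mask: StructureMask, d_pres: float
) -> tuple[float, float]:
    """Mean signed voxel difference (evaluated - reference) over a mask.

    Returns ``(ME in Gy, ME in % of d_pres)``.  Both doses must already
    live on the same grid (resample first) and the mask must be non-empty.
    """
    if not eval_dose.same_geometry(ref_dose):
        raise ValueError("dose grids differ; resample onto a common grid first")
    if mask.mask.shape != ref_dose.shape:
        raise ValueError("mask geometry does not match the dose grid")
    if mask.is_empty():
        raise ValueError(f"structure {mask.name!r} is empty")
    me_gy = float((eval_dose.values[mask.mask] - ref_dose.values[mask.mask]).mean())
    return me_gy, 100.0 * me_gy / d_pres


# ---------------------------------------------------------------------------
# gamma analysis
# ---------------------------------------------------------------------------

def _offset_lattice(criteria: GammaCriteria) -> tuple[np.ndarray, np.ndarray]:
    """Search offsets (mm) within gamma_cap*Delta, sorted by distance."""
    step = criteria.interp_fraction * criteria.distance_mm
    radius = criteria.gamma_cap * criteria.distance_mm
    m = int(np.floor(radius / step + 1e-9))
    axis = np.arange(-m, m + 1) * step
    ox, oy, oz = np.meshgrid(axis, axis, axis, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    norms = np.linalg.norm(offsets, axis=1)
    keep = norms <= radius + 1e-9
    offsets, norms = offsets[keep], norms[keep]
    order = np.argsort(norms, kind="stable")
    return offsets[order], norms[order]


def _included_reference(ref_dose: Volume, criteria: GammaCriteria):
    peak = float(ref_dose.values.max())
    if peak <= 0:
        raise ValueError("reference dose is non-positive everywhere; threshold undefined")
    threshold = criteria.threshold_fraction * peak
    included = ref_dose.values >= threshold
    if not included.any():
        raise ValueError("all reference voxels fall below the low-dose threshold")
    idx = np.argwhere(included)
    positions = ref_dose.index_to_physical(idx.astype(float))
    return included, positions, ref_dose.values[included]


def _sample_eval(eval_dose: Volume, points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear samples of the evaluated dose; validity flags for points
    outside the grid support (those contribute no gamma candidate)."""
    fid = eval_dose.physical_to_index(points_mm)
    upper = np.asarray(eval_dose.shape, dtype=float) - 1.0
    valid = np.all((fid >= -1e-9) & (fid <= upper + 1e-9), axis=1)
    samples = ndimage.map_coordinates(
        np.asarray(eval_dose.values, dtype=float),
        np.clip(fid, 0.0, upper).T,
        order=1,
        mode="nearest",
        prefilter=False,
    )
    return samples, valid


def _finalize(gamma2: np.ndarray, included: np.ndarray, cap: float, shape) -> tuple[Volume, float]:
    gamma_flat = np.sqrt(gamma2)
    gamma_flat = np.minimum(gamma_flat, cap)
    pass_rate = 100.0 * float(np.mean(gamma_flat <= 1.0))
    return gamma_flat, pass_rate


def gamma_map(
    ref_dose: Volume, eval_dose: Volume, criteria: GammaCriteria | None = None
) -> tuple[Volume, float]:
    """3D local gamma of ``eval_dose`` against ``ref_dose``.

    Returns ``(gamma volume, pass rate in %)``.  Excluded (below-threshold)
    voxels carry NaN in the gamma volume; the pass rate is over included
    voxels only.  Exact on the same interpolation lattice as
    :func:`gamma_bruteforce` - the distance-sorted search is a pruning, not
    an approximation.
    """
    criteria = criteria or GammaCriteria()
    if ref_dose.frame_id != eval_dose.frame_id:
        raise ValueError("doses live in different frames")
    offsets, norms = _offset_lattice(criteria)
    included, positions, ref_vals = _included_reference(ref_dose, criteria)

    n = ref_vals.size
    denom2 = (criteria.dose_percent / 100.0 * ref_vals) ** 2
    cap2 = criteria.gamma_cap**2
    gamma2 = np.full(n, np.inf)
    active = np.arange(n)
    delta2 = criteria.distance_mm**2

    for o, norm in zip(offsets, norms):
        spatial2 = norm**2 / delta2
        still = gamma2[active] > spatial2
        active = active[still]
        if active.size == 0:
            break
        samples, valid = _sample_eval(eval_dose, positions[active] + o)
        if valid.any():
            sel = active[valid]
            g2 = spatial2 + (samples[valid] - ref_vals[sel]) ** 2 / denom2[sel]
            np.minimum.at(gamma2, sel, g2)

    gamma_flat, pass_rate = _finalize(gamma2, included, criteria.gamma_cap, ref_dose.shape)
    out = np.full(ref_dose.shape, np.nan)
    out[included] = gamma_flat
    return ref_dose.with_values(out), pass_rate


def gamma_bruteforce(
    ref_dose: Volume, eval_dose: Volume, criteria: GammaCriteria | None = None
) -> tuple[Volume, float]:
    """Exhaustive gamma over the full interpolation lattice (test oracle).

    Identical contract to :func:`gamma_map`, with no search pruning.
    Intended for small grids (<= 32^3).
    """
    criteria = criteria or GammaCriteria()
    if ref_dose.frame_id != eval_dose.frame_id:
        raise ValueError("doses live in different frames")
    offsets, norms = _offset_lattice(criteria)
    included, positions, ref_vals = _included_reference(ref_dose, criteria)

    denom2 = (criteria.dose_percent / 100.0 * ref_vals) ** 2
    delta2 = criteria.distance_mm**2
    gamma2 = np.full(ref_vals.size, np.inf)
    for o, norm in zip(offsets, norms):
        samples, valid = _sample_eval(eval_dose, positions + o)
        g2 = norm**2 / delta2 + (samples - ref_vals) ** 2 / denom2
        g2[~valid] = np.inf
        np.minimum(gamma2, g2, out=gamma2)

    gamma_flat, pass_rate = _finalize(gamma2, included, criteria.gamma_cap, ref_dose.shape)
    out = np.full(ref_dose.shape, np.nan)
    out[included] = gamma_flat
    return ref_dose.with_values(out), pass_rate
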