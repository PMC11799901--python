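"""Threshold-based structures and dose-volume histogram (DVH) metrics.

Structures follow the HU-window convention used when no clinician contours
are available: brain = HU in [-100, 100], skull = HU >= 100, both inside
the body.  Note the deliberate double membership at exactly 100 HU - a
voxel at 100 HU belongs to *both* windows, kept as a literal reading of the
interval definitions.

DVH point metrics are Dx% (minimum dose to the hottest x% of the volume)
and Dmean.  The interpolation convention is: sort voxel doses descending,
assign voxel k (1-based) cumulative volume fraction k/N, interpolate
linearly between those points; x below 100/N returns the maximum voxel
dose.  Metric differences are expressed in % of the prescribed dose,
evaluated minus reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from sctqa.geometry import StructureMask, Volume

__all__ = [
    "DVH",
    "DVHMetrics",
    "body_mask",
    "threshold_structures",
    "dose_at_volume",
    "mean_dose",
    "dvh_metrics",
    "delta_dx",
]

BRAIN_WINDOW_HU = (-100.0, 100.0)
SKULL_FLOOR_HU = 100.0
BODY_FLOOR_HU = -300.0


@dataclass
class DVH:
    """Differential voxel-dose record of one structure."""

    structure: str
    sorted_doses: np.ndarray  # descending, Gy
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        doses = np.asarray(self.sorted_doses, dtype=float).ravel()
        if doses.size == 0:
            raise ValueError(f"empty DVH for structure {self.structure!r}")
        self.sorted_doses = np.sort(doses)[::-1]

    @classmethod
    def from_volume(cls, dose: Volume, mask: StructureMask) -> "DVH":
        if mask.mask.shape != dose.shape:
            raise ValueError("mask geometry does not match the dose grid")
        if mask.is_empty():
            raise ValueError(f"structure {mask.name!r} is empty")
        return cls(mask.name, dose.values[mask.mask], dose.voxel_volume_mm3)

    @property
    def n_voxels(self) -> int:
        return int(self.sorted_doses.size)

    def to_curve(self) -> pd.DataFrame:
        """Cumulative DVH as (dose_gy, fractional_volume) for CSV export."""
        n = self.n_voxels
        return pd.DataFrame(
            {"dose_gy": self.sorted_doses, "fractional_volume": np.arange(1, n + 1) / n}
        )


@dataclass(frozen=True)
class DVHMetrics:
    """The four point metrics of a cumulative DVH, in Gy."""

    d2: float
    d95: float
    d98: float
    dmean: float

    def as_dict(self) -> dict[str, float]:
        return {"D2%": self.d2, "D95%": self.d95, "D98%": self.d98, "Dmean": self.dmean}


def body_mask(ct: Volume, floor_hu: float = BODY_FLOOR_HU) -> np.ndarray:
    """Largest connected component of HU > floor: the patient's body.

    Excludes exterior air (and couch-like debris) from HU-window structures.
    """
    fg = ct.values > floor_hu
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no voxels above the body HU floor")
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def threshold_structures(ct: Volume) -> tuple[StructureMask, StructureMask]:
    """Brain and skull masks by HU windowing of a CT, inside the body.

    brain = {-100 <= HU <= 100}, skull = {HU >= 100}; a voxel at exactly
    100 HU is a member of both.  Raises with an HU summary if either
    window comes back empty.
    """
    body = body_mask(ct)
    hu = ct.values
    brain = (hu >= BRAIN_WINDOW_HU[0]) & (hu <= BRAIN_WINDOW_HU[1]) & body
    skull = (hu >= SKULL_FLOOR_HU) & body
    if not brain.any() or not skull.any():
        qs = np.percentile(hu[body], [0, 25, 50, 75, 100]) if body.any() else []
        raise ValueError(
            f"thresholding produced an empty structure; in-body HU quartiles: {np.round(qs, 1)}"
        )
    return (
        StructureMask("Brain", brain, source="threshold"),
        StructureMask("Skull", skull, source="threshold"),
    )


def dose_at_volume(dvh: DVH, x: float) -> float:
    """Dx%: the dose received by at least x% of the structure volume.

    Linear interpolation on the descending sorted voxel doses with voxel k
    (1-based) at cumulative volume fraction k/N; x below 100/N returns the
    maximum voxel dose, D100% the minimum.
    """
    if not 0.0 < x <= 100.0:
        raise ValueError(f"x must be in (0, 100], got {x}")
    d = dvh.sorted_doses
    n = d.size
    fractions = 100.0 * np.arange(1, n + 1) / n
    return float(np.interp(x, fractions, d))


def mean_dose(dvh: DVH) -> float:
    """Arithmetic mean voxel dose (equal voxel volumes)."""
    return float(dvh.sorted_doses.mean())


def dvh_metrics(dvh: DVH) -> DVHMetrics:
    return DVHMetrics(
        d2=dose_at_volume(dvh, 2.0),
        d95=dose_at_volume(dvh, 95.0),
        d98=dose_at_volume(dvh, 98.0),
        dmean=mean_dose(dvh),
    )


def delta_dx(eval_metrics: DVHMetrics, ref_metrics: DVHMetrics, d_pres: float) -> dict[str, float]:
    """Per-metric (evaluated - reference) / prescription, in %."""
    if d_pres <= 0:
        raise ValueError("d_pres must be > 0")
    e, r = eval_metrics.as_dict(), ref_metrics.as_dict()
    return {name: 100.0 * (e[name] - r[name]) / d_pres for name in e}
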