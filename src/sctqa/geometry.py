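"""Geometry-aware volume container and resampling.

Every stage of the pipeline (phantom generation, dose calculation, DVH and
gamma analysis, DRR projection) exchanges data as a :class:`Volume`: a 3D
scalar grid (HU for images, Gy for dose) with full spatial geometry in a
patient-based, right-handed millimetre frame.

Conventions
-----------
* Array axis order is ``(x, y, z)``: ``values[i, j, k]``.
* Voxel-centre addressing, 0-based indices: the physical position of voxel
  ``(i, j, k)`` is ``origin + axes @ (i*sx, j*sy, k*sz)`` exactly, so voxel
  ``(0, 0, 0)`` sits at ``origin``.
* ``axes`` is an orthonormal direction matrix whose *columns* are the
  physical directions of the three index axes.
* ``frame_id`` is an opaque label tying volumes to a common physical frame;
  operations that compare voxels refuse to mix frames silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = ["Volume", "StructureMask", "resample", "FrameMismatchError", "GeometryError"]


class GeometryError(ValueError):
    """Raised when a Volume's spatial metadata is inconsistent."""


class FrameMismatchError(ValueError):
    """Raised when two volumes that must share a physical frame do not."""


@dataclass
class Volume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar samples at voxel centres (HU for images, Gy for dose).
    origin : array-like of 3 floats
        Physical position (mm) of the centre of voxel ``(0, 0, 0)``.
    spacing : array-like of 3 floats
        Per-axis voxel size in mm, strictly positive.
    axes : (3, 3) ndarray, optional
        Orthonormal direction matrix (columns = index-axis directions).
        Defaults to the identity.
    frame_id : str
        Label of the physical frame this volume lives in.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    frame_id: str = "default"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError(f"values must be 3D, got shape {self.values.shape}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if abs(abs(np.linalg.det(self.axes)) - 1.0) > 1e-9 or not np.allclose(
            self.axes.T @ self.axes, np.eye(3), atol=1e-9
        ):
            raise GeometryError("axes must be orthonormal (|det| = 1 within 1e-9)")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, ijk: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of (possibly fractional) voxel indices.

        ``ijk`` has shape ``(..., 3)``; the result has the same shape.
        """
        ijk = np.asarray(ijk, dtype=float)
        return self.origin + (ijk * self.spacing) @ self.axes.T

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of physical points (inverse of above)."""
        xyz = np.asarray(xyz, dtype=float)
        return ((xyz - self.origin) @ self.axes) / self.spacing

    def same_geometry(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.axes, other.axes, atol=tol)
        )

    def with_values(self, values: np.ndarray) -> "Volume":
        """A new Volume sharing this geometry with different samples."""
        if values.shape != self.shape:
            raise GeometryError(f"shape {values.shape} != grid shape {self.shape}")
        return replace(self, values=values)

    def copy(self) -> "Volume":
        return replace(self, values=self.values.copy())


@dataclass
class StructureMask:
    """A named boolean mask on a stated Volume geometry.

    ``source`` records provenance: ``contour`` (rasterised RTSTRUCT),
    ``threshold`` (HU windowing), or ``synthetic`` (planted compartment).
    """

    name: str
    mask: np.ndarray
    source: Literal["contour", "threshold", "synthetic"] = "synthetic"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {self.mask.shape}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def is_empty(self) -> bool:
        return not self.mask.any()


def _index_affine(source: Volume, target: Volume) -> tuple[np.ndarray, np.ndarray]:
    """Matrix/offset mapping target voxel indices to source voxel indices."""
    a = (source.axes.T @ target.axes) * (target.spacing[None, :] / source.spacing[:, None])
    b = (source.axes.T @ (target.origin - source.origin)) / source.spacing
    return a, b


def resample(
    volume: Volume,
    target: Volume,
    mode: Literal["trilinear", "nearest"] = "trilinear",
    fill: float | None = None,
) -> Volume:
    """Resample ``volume`` onto the geometry of ``target``.

    ``trilinear`` is for scalar dose/HU, ``nearest`` for label/mask content.
    Voxels of the target grid outside the support of ``volume`` receive
    ``fill`` (default: -1000 — air — which callers override with 0 for dose).

    Raises :class:`FrameMismatchError` if the two volumes are not tied to the
    same physical frame; relate them first with a known rigid transform
    (see :mod:`sctqa.positioning`).
    """
    if volume.frame_id != target.frame_id:
        raise FrameMismatchError(
            f"cannot resample across frames {volume.frame_id!r} -> {target.frame_id!r}"
        )
    if fill is None:
        fill = -1000.0
    if volume.same_geometry(target):
        return Volume(volume.values.copy(), target.origin, target.spacing, target.axes, target.frame_id)
    order = 1 if mode == "trilinear" else 0
    matrix, offset = _index_affine(volume, target)
    out = ndimage.affine_transform(
        np.asarray(volume.values, dtype=float),
        matrix,
        offset=offset,
        output_shape=target.shape,
        order=order,
        mode="constant",
        cval=fill,
        prefilter=False,
    )
    return Volume(out, target.origin, target.spacing, target.axes, target.frame_id)
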