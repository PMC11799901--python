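"""DRR-based 2D/2D patient positioning and 3D rigid registration.

Emulates a stereoscopic kV positioning chain: digitally reconstructed
radiographs (DRRs) are cast through the CT (or sCT) volume with the same
Siddon ray tracer as the dose engine; an orthogonal kV pair acquired at an
unknown patient pose is registered against DRRs of the posed volume by
maximising normalised cross-correlation (NCC), driven by bony structures
(soft tissue is suppressed below a HU floor before projection, emulating
automatic bone-based registration).

The positioning QA quantity is the per-axis difference between the couch
correction found with the CT and with the sCT, after subtracting the static
sCT/CT registration offset so that only positioning-relevant discrepancies
remain.  Differences are composed additively per axis (small-angle
approximation; the error is < 0.01 degrees for rotations up to 5 degrees).

Pose convention: translations (lateral x, longitudinal y, vertical z) in mm
applied after intrinsic rotations about the lateral -> longitudinal ->
vertical axes at the isocenter, i.e. ``p' = R (p - c) + c + t``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from sctqa._interp import affine_trilinear
from sctqa._siddon import wepl_to_points
from sctqa.dose import DensityCalibration, hu_to_density
from sctqa.geometry import Volume

__all__ = [
    "ViewGeometry",
    "ProjectionGeometry",
    "RigidPose",
    "PositioningDelta",
    "RegistrationResult",
    "generate_drr",
    "simulate_kv_pair",
    "register_2d2d",
    "register_3d_rigid",
    "positioning_delta",
]

#: HU below which tissue is ignored when bone weighting is on
BONE_HU_FLOOR = 150.0
#: NCC below which a registration is reported as failed
SIMILARITY_FLOOR = 0.2


@dataclass(frozen=True)
class RigidPose:
    """Six-parameter rigid pose about a stated isocenter."""

    translations_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for r in self.rotations_deg:
            if not -180.0 < r <= 180.0:
                raise ValueError("rotations must lie in (-180, 180] degrees")

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls()

    @classmethod
    def from_vector(cls, v) -> "RigidPose":
        v = np.asarray(v, dtype=float)
        return cls(tuple(v[:3]), tuple(v[3:6]))

    def as_vector(self) -> np.ndarray:
        return np.array([*self.translations_mm, *self.rotations_deg])

    def rotation(self) -> Rotation:
        return Rotation.from_euler("XYZ", self.rotations_deg, degrees=True)

    def apply(self, points_mm: np.ndarray, isocenter_mm) -> np.ndarray:
        """Transform physical points: rotate about the isocenter, translate."""
        c = np.asarray(isocenter_mm, dtype=float)
        return self.rotation().apply(np.asarray(points_mm, dtype=float) - c) + c + np.asarray(
            self.translations_mm
        )

    def apply_inverse(self, points_mm: np.ndarray, isocenter_mm) -> np.ndarray:
        c = np.asarray(isocenter_mm, dtype=float)
        shifted = np.asarray(points_mm, dtype=float) - c - np.asarray(self.translations_mm)
        return self.rotation().inv().apply(shifted) + c


@dataclass(frozen=True)
class ViewGeometry:
    """One kV view: point source and a flat virtual detector.

    The detector plane is placed through the isocenter (unit magnification
    at the isocenter plane), which keeps couch shifts and image shifts on
    the same millimetre scale.
    """

    source_position_mm: tuple[float, float, float]
    detector_center_mm: tuple[float, float, float]
    detector_axes: tuple[tuple[float, float, float], tuple[float, float, float]]
    pixel_spacing_mm: float = 2.0
    detector_size_px: tuple[int, int] = (112, 112)

    def pixel_positions(self, stride: int = 1) -> np.ndarray:
        """Physical positions of pixel centres, shape (nu, nv, 3)."""
        nu, nv = self.detector_size_px
        u_axis = np.asarray(self.detector_axes[0], dtype=float)
        v_axis = np.asarray(self.detector_axes[1], dtype=float)
        center = np.asarray(self.detector_center_mm, dtype=float)
        us = (np.arange(nu)[::stride] - (nu - 1) / 2.0) * self.pixel_spacing_mm
        vs = (np.arange(nv)[::stride] - (nv - 1) / 2.0) * self.pixel_spacing_mm
        uu, vv = np.meshgrid(us, vs, indexing="ij")
        return center + uu[..., None] * u_axis + vv[..., None] * v_axis


@dataclass(frozen=True)
class ProjectionGeometry:
    """An orthogonal pair of kV views sharing one isocenter."""

    views: tuple[ViewGeometry, ViewGeometry]
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        c = np.asarray(self.isocenter_mm, dtype=float)
        dirs = []
        for view in self.views:
            d = c - np.asarray(view.source_position_mm, dtype=float)
            dirs.append(d / np.linalg.norm(d))
        angle = np.degrees(np.arccos(np.clip(abs(np.dot(dirs[0], dirs[1])), 0, 1)))
        if abs(angle - 90.0) > 0.1:
            raise ValueError(f"view axes must be orthogonal within 0.1 deg, got {angle:.3f}")

    @classmethod
    def default_orthogonal(
        cls,
        isocenter_mm=(0.0, 0.0, 0.0),
        sad_mm: float = 1000.0,
        detector_size_px: tuple[int, int] = (112, 112),
        pixel_spacing_mm: float = 2.0,
    ) -> "ProjectionGeometry":
        """An AP view (source on +y) and a lateral view (source on +x)."""
        c = np.asarray(isocenter_mm, dtype=float)
        ap = ViewGeometry(
            source_position_mm=tuple(c + np.array([0.0, sad_mm, 0.0])),
            detector_center_mm=tuple(c),
            detector_axes=((1.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
            pixel_spacing_mm=pixel_spacing_mm,
            detector_size_px=detector_size_px,
        )
        lat = ViewGeometry(
            source_position_mm=tuple(c + np.array([sad_mm, 0.0, 0.0])),
            detector_center_mm=tuple(c),
            detector_axes=((0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
            pixel_spacing_mm=pixel_spacing_mm,
            detector_size_px=detector_size_px,
        )
        return cls(views=(ap, lat), isocenter_mm=tuple(c))


@dataclass(frozen=True)
class PositioningDelta:
    """Per-axis CT-vs-sCT positioning difference after offset subtraction."""

    shift_mm: tuple[float, float, float]
    rotation_deg: tuple[float, float, float]


@dataclass
class RegistrationResult:
    """Pose estimate plus diagnostics from an NCC registration."""

    pose: RigidPose
    similarity: float
    multi_optimum: bool = False
    status: str = "ok"  # or "failed"


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def _attenuation(volume: Volume, bone_weighting: bool, cal: DensityCalibration | None) -> np.ndarray:
    density = np.asarray(hu_to_density(volume.values, cal or DensityCalibration()), dtype=np.float64)
    if bone_weighting:
        density = np.where(volume.values < BONE_HU_FLOOR, 0.0, density)
    else:
        # air contributes nothing to a radiograph
        density = np.where(density < 0.005, 0.0, density)
    return np.ascontiguousarray(density)


def _project(
    attenuation: np.ndarray,
    volume: Volume,
    view: ViewGeometry,
    pose: RigidPose | None = None,
    isocenter_mm=None,
    stride: int = 1,
) -> np.ndarray:
    """Line integrals source -> (beyond) each pixel through the volume.

    A non-identity ``pose`` projects the volume as if it had been moved by
    that pose: the ray endpoints are carried into the volume's native frame
    by the inverse transform, which is equivalent and avoids resampling.
    """
    src = np.asarray(view.source_position_mm, dtype=float)
    pix = view.pixel_positions(stride=stride)
    shape2d = pix.shape[:2]
    # extend rays past the detector plane so the far half of the head is crossed
    far = src + 2.0 * (pix.reshape(-1, 3) - src)
    srcs = np.broadcast_to(src, far.shape).copy()
    if pose is not None and not np.allclose(pose.as_vector(), 0.0):
        far = pose.apply_inverse(far, isocenter_mm)
        srcs = pose.apply_inverse(srcs, isocenter_mm)
    src_local0 = (srcs - volume.origin) @ volume.axes
    far_local = (far - volume.origin) @ volume.axes
    sx, sy, sz = (float(s) for s in volume.spacing)
    # sources may differ per ray after a pose transform -> loop via kernel with per-ray source
    out = np.empty(far_local.shape[0])
    # all rays share the same source for identity poses; the kernel handles one
    # source, so group: after a rigid transform all transformed sources coincide.
    out = wepl_to_points(attenuation, sx, sy, sz, np.ascontiguousarray(src_local0[0]), np.ascontiguousarray(far_local))
    return out.reshape(shape2d)


def generate_drr(
    volume: Volume,
    view: ViewGeometry,
    bone_weighting: bool = False,
    cal: DensityCalibration | None = None,
) -> np.ndarray:
    """DRR of one view: per-pixel radiological line integral (mm WEPL).

    With ``bone_weighting`` the attenuation of voxels below
    ``BONE_HU_FLOOR`` (150 HU) is zeroed, leaving a bone-only projection.
    Doubling every density doubles every pixel (line integrals are linear).
    """
    attenuation = _attenuation(volume, bone_weighting, cal)
    img = _project(attenuation, volume, view)
    if not img.any():
        warnings.warn("volume lies outside the view frustum; DRR is all zero", stacklevel=2)
    return img


def simulate_kv_pair(
    ct: Volume,
    applied_pose: RigidPose,
    geom: ProjectionGeometry,
    noise_level: float = 0.0,
    seed: int = 0,
    bone_weighting: bool = True,
    cal: DensityCalibration | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated orthogonal kV pair of a patient at ``applied_pose``.

    The patient's attenuation field (bone-weighted by default, emulating
    the bone-enhanced image processing of automatic registration chains)
    is resampled under the pose (trilinear) and projected per view;
    multiplicative Gaussian noise of relative sigma ``noise_level`` is
    applied.  Deterministic for a fixed seed.
    """
    att_vol = ct.with_values(_attenuation(ct, bone_weighting, cal))
    posed = _resample_under_pose(att_vol, applied_pose, geom.isocenter_mm, cval=0.0)
    attenuation = np.ascontiguousarray(posed.values)
    rng = np.random.default_rng(seed)
    images = []
    for view in geom.views:
        img = _project(attenuation, posed, view)
        if noise_level > 0:
            img = img * (1.0 + rng.normal(0.0, noise_level, size=img.shape))
        images.append(img)
    return images[0], images[1]


def _resample_under_pose(volume: Volume, pose: RigidPose, isocenter_mm, cval: float = -1000.0) -> Volume:
    """The volume as it would be acquired after moving it by ``pose``."""
    if np.allclose(pose.as_vector(), 0.0):
        return volume.copy()
    c = np.asarray(isocenter_mm, dtype=float)
    rot = pose.rotation().as_matrix()
    t = np.asarray(pose.translations_mm)
    axes = volume.axes
    # output grid point x samples the original volume at R^T (x - c - t) + c;
    # composed in index space: idx_in = a_mat @ idx_out + b
    a_mat = (axes.T @ rot.T @ axes) * (volume.spacing[None, :] / volume.spacing[:, None])
    b = (axes.T @ (rot.T @ (volume.origin - c - t) + c - volume.origin)) / volume.spacing
    out = affine_trilinear(
        np.ascontiguousarray(volume.values, dtype=np.float64),
        np.ascontiguousarray(a_mat),
        np.ascontiguousarray(b),
        volume.shape,
        float(cval),
    )
    return volume.with_values(out)


# ---------------------------------------------------------------------------
# similarity + registration
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def _fft_shift_estimate(reference: np.ndarray, moved: np.ndarray) -> tuple[float, float]:
    """Subpixel 2D shift of ``moved`` relative to ``reference`` (in pixels),
    by cross-correlation peak with parabolic interpolation."""
    f = np.fft.rfft2(reference - reference.mean())
    g = np.fft.rfft2(moved - moved.mean())
    xc = np.fft.irfft2(np.conj(f) * g, s=reference.shape)
    peak = np.unravel_index(np.argmax(xc), xc.shape)
    shifts = []
    for axis, p in enumerate(peak):
        n = xc.shape[axis]
        idx = [peak[0], peak[1]]
        vals = []
        for d in (-1, 0, 1):
            idx[axis] = (p + d) % n
            vals.append(xc[tuple(idx)])
        denom = vals[0] - 2 * vals[1] + vals[2]
        frac = 0.0 if denom == 0 else 0.5 * (vals[0] - vals[2]) / denom
        s = p + frac
        if s > n / 2:
            s -= n
        shifts.append(s)
    return shifts[0], shifts[1]


def register_2d2d(
    kv_pair: tuple[np.ndarray, np.ndarray],
    volume: Volume,
    geom: ProjectionGeometry,
    bone_weighting: bool = True,
    cal: DensityCalibration | None = None,
    rotation_search_deg: float = 5.0,
    rotation_step_deg: float = 1.0,
    refine_maxiter: tuple[int, int] = (120, 60),
) -> RegistrationResult:
    """Recover the 6-parameter pose that aligns DRRs with a kV pair.

    Strategy: (1) per-view FFT cross-correlation against identity DRRs
    initialises the three translations; (2) a coarse 1-degree lattice over
    the three rotations (at reduced detector resolution) initialises the
    rotations and flags near-degenerate optima; (3) derivative-free local
    refinement (Nelder-Mead) of all six parameters at full resolution.

    Reports the final mean NCC; a similarity below ``SIMILARITY_FLOOR``
    yields status ``"failed"``.  ``multi_optimum`` is set when a second
    coarse rotation optimum lies within 1% similarity of the best but more
    than 2 degrees away (e.g. for nearly spherically symmetric anatomy).
    """
    attenuation = _attenuation(volume, bone_weighting, cal)
    kv0, kv1 = kv_pair
    iso = geom.isocenter_mm

    # --- stage 1: translations from per-view image shifts ---------------
    t_est = np.zeros(3)
    axis_weight = np.zeros(3)
    for view, kv in zip(geom.views, (kv0, kv1)):
        drr = _project(attenuation, volume, view)
        du, dv = _fft_shift_estimate(drr, kv)
        u_axis = np.asarray(view.detector_axes[0])
        v_axis = np.asarray(view.detector_axes[1])
        shift_mm = (du * u_axis + dv * v_axis) * view.pixel_spacing_mm
        t_est += shift_mm
        axis_weight += np.abs(u_axis) + np.abs(v_axis)
    t_est = np.divide(t_est, axis_weight, out=np.zeros(3), where=axis_weight > 0)

    # --- stage 2: coarse rotation lattice at reduced resolution ---------
    stride = 4
    kv_coarse = (kv0[::stride, ::stride], kv1[::stride, ::stride])
    angles = np.arange(-rotation_search_deg, rotation_search_deg + 1e-9, rotation_step_deg)

    def coarse_similarity(rx, ry, rz) -> float:
        pose = RigidPose(tuple(t_est), (rx, ry, rz))
        s = 0.0
        for view, kv in zip(geom.views, kv_coarse):
            drr = _project(attenuation, volume, view, pose=pose, isocenter_mm=iso, stride=stride)
            s += _ncc(kv, drr)
        return s / 2.0

    best = (-np.inf, (0.0, 0.0, 0.0))
    entries = []
    for rx in angles:
        for ry in angles:
            for rz in angles:
                s = coarse_similarity(rx, ry, rz)
                entries.append((s, (rx, ry, rz)))
                if s > best[0]:
                    best = (s, (rx, ry, rz))
    # strongest rival optimum well separated from the best
    rival = None
    multi = False
    for s, r in sorted(entries, reverse=True):
        if np.max(np.abs(np.subtract(r, best[1]))) > 2.0:
            rival = (s, r)
            multi = s >= best[0] * (1.0 - 0.01)
            break

    # --- stage 3: local refinement with the exact acquisition model ------
    # The coarse stages project the static volume along inversely-posed
    # rays, which is fast but optically not identical to how a kV image is
    # formed (attenuation resampled under the pose, then projected); that
    # small mismatch biases the optimum by a few tenths of a degree in the
    # flatter rotation axes.  The refinement therefore resamples the
    # attenuation field under each candidate pose and projects it, so the
    # objective peaks exactly at the acquisition pose.
    att_vol = volume.with_values(attenuation)

    def negative_similarity(v: np.ndarray, stride: int) -> float:
        pose = RigidPose.from_vector(v)
        posed = _resample_under_pose(att_vol, pose, iso, cval=0.0)
        att = np.ascontiguousarray(posed.values)
        s = 0.0
        for view, kv in zip(geom.views, (kv0, kv1)):
            drr = _project(att, posed, view, stride=stride)
            s += _ncc(kv[::stride, ::stride], drr)
        return -s / 2.0

    # refine from the best coarse pose and, to guard against a wrong basin
    # on flat rotation landscapes, from the strongest well-separated rival
    starts = [(np.array([*t_est, *best[1]]), refine_maxiter[0])]
    if rival is not None and rival[0] >= best[0] * 0.98:
        starts.append((np.array([*t_est, *rival[1]]), max(refine_maxiter[0] * 2 // 3, 1)))
    phase_a = []
    for x0, maxiter in starts:
        r = optimize.minimize(
            negative_similarity,
            x0,
            args=(2,),
            method="Nelder-Mead",
            options={"xatol": 5e-3, "fatol": 1e-10, "maxiter": maxiter, "initial_simplex": _simplex(x0)},
        )
        phase_a.append(r)
    winner = min(phase_a, key=lambda r: r.fun)
    res = optimize.minimize(
        negative_similarity,
        winner.x,
        args=(1,),
        method="Nelder-Mead",
        options={
            "xatol": 2e-3,
            "fatol": 1e-10,
            "maxiter": refine_maxiter[1],
            "initial_simplex": _simplex(winner.x, t_step=0.05, r_step=0.05),
        },
    )
    similarity = -float(res.fun)
    pose = RigidPose.from_vector(res.x)
    status = "ok" if similarity >= SIMILARITY_FLOOR else "failed"
    return RegistrationResult(pose=pose, similarity=similarity, multi_optimum=multi, status=status)


def _simplex(x0: np.ndarray, t_step: float = 0.5, r_step: float = 0.5) -> np.ndarray:
    steps = np.array([t_step] * 3 + [r_step] * (len(x0) - 3))
    simplex = np.tile(x0, (len(x0) + 1, 1))
    for i in range(len(x0)):
        simplex[i + 1, i] += steps[i]
    return simplex


def register_3d_rigid(moving: Volume, fixed: Volume) -> RegistrationResult:
    """6-parameter rigid registration maximising NCC on HU, coarse-to-fine.

    The returned pose moves ``moving`` onto ``fixed`` (applied about the
    centre of the fixed grid).  A first pass runs on a 4x downsampled,
    smoothed pyramid level, a second at full resolution.
    """
    center = fixed.index_to_physical((np.asarray(fixed.shape, dtype=float) - 1) / 2.0)

    def level(vol: Volume, factor: int) -> Volume:
        if factor == 1:
            return vol
        sm = ndimage.gaussian_filter(np.asarray(vol.values, dtype=float), sigma=factor / 2.0)
        return Volume(
            sm[::factor, ::factor, ::factor],
            vol.origin,
            vol.spacing * factor,
            vol.axes,
            vol.frame_id,
        )

    def negative_ncc(v: np.ndarray, mov: Volume, fix: Volume) -> float:
        pose = RigidPose.from_vector(v)
        resampled = _resample_posed_onto(mov, fix, pose, center)
        return -_ncc(resampled, fix.values)

    x = np.zeros(6)
    for factor, xatol in ((4, 0.05), (1, 2e-3)):
        mov, fix = level(moving, factor), level(fixed, factor)
        res = optimize.minimize(
            negative_ncc,
            x,
            args=(mov, fix),
            method="Nelder-Mead",
            options={
                "xatol": xatol,
                "fatol": 1e-10,
                "maxiter": 800,
                "initial_simplex": _simplex(x, t_step=2.0 / factor if factor > 1 else 0.25, r_step=1.0 / factor if factor > 1 else 0.25),
            },
        )
        x = res.x
    similarity = -float(res.fun)
    status = "ok" if similarity >= SIMILARITY_FLOOR else "failed"
    return RegistrationResult(pose=RigidPose.from_vector(x), similarity=similarity, status=status)


def _resample_posed_onto(moving: Volume, fixed: Volume, pose: RigidPose, isocenter_mm) -> np.ndarray:
    """Sample ``moving`` (moved by pose) on the fixed grid."""
    c = np.asarray(isocenter_mm, dtype=float)
    rot = pose.rotation().as_matrix()
    t = np.asarray(pose.translations_mm)
    # fixed index -> physical -> inverse pose -> moving index
    lin_fix = fixed.axes * fixed.spacing[None, :]
    a_world = rot.T @ lin_fix
    b_world = rot.T @ (fixed.origin - c - t) + c
    lin_mov_inv = (moving.axes / moving.spacing[:, None]).T  # maps world deltas to index
    a_mat = lin_mov_inv @ a_world
    b = lin_mov_inv @ (b_world - moving.origin)
    return affine_trilinear(
        np.ascontiguousarray(moving.values, dtype=np.float64),
        np.ascontiguousarray(a_mat),
        np.ascontiguousarray(b),
        fixed.shape,
        -1000.0,
    )


def save_drr(image: np.ndarray, path, geometry: ViewGeometry | None = None) -> None:
    """Write a DRR as 16-bit PNG (max-normalised) plus a JSON geometry sidecar."""
    import json
    from pathlib import Path as _P

    from PIL import Image

    path = _P(path)
    peak = float(image.max())
    scaled = np.zeros_like(image) if peak <= 0 else image / peak
    Image.fromarray((scaled.T * 65535).astype(np.uint16)).save(path)
    if geometry is not None:
        meta = {
            "source_position_mm": list(geometry.source_position_mm),
            "detector_center_mm": list(geometry.detector_center_mm),
            "detector_axes": [list(a) for a in geometry.detector_axes],
            "pixel_spacing_mm": geometry.pixel_spacing_mm,
            "detector_size_px": list(geometry.detector_size_px),
            "normalisation_peak_wepl_mm": peak,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def positioning_delta(
    ct_pose: RigidPose, sct_pose: RigidPose, sct_ct_offset: RigidPose | None = None
) -> PositioningDelta:
    """Per-axis positioning difference ``(sct - ct) - offset``.

    ``sct_ct_offset`` is the static sCT/CT registration pose, subtracted so
    a systematic generator offset does not masquerade as a positioning
    error.  Additive per-axis composition (small-angle approximation).
    """
    offset = sct_ct_offset or RigidPose.identity()
    d = sct_pose.as_vector() - ct_pose.as_vector() - offset.as_vector()
    return PositioningDelta(shift_mm=tuple(d[:3]), rotation_deg=tuple(d[3:6]))
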