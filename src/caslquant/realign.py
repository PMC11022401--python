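"""Rigid-body realignment of image time series.

Each frame is registered to a reference frame with a 6-parameter rigid
transform (3 translations in mm, 3 rotations in degrees) estimated by
minimising the sum of squared intensity differences, the classical
least-squares criterion for within-modality motion correction.  Rotations
are applied about the volume centre in physical (mm) coordinates, so the
anisotropic voxel size of a multi-slice EPI readout is handled correctly.
Optimisation is a derivative-free local (Powell) search started from the
identity, which suits the small inter-frame motion of a restrained subject.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .geometry import VolumeGeometry
from .io import ASLSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """Translations (mm) and rotations (degrees, about x/y/z through the centre)."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def as_vector(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "RigidTransform":
        return cls(*[float(x) for x in v])

    def is_identity(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.as_vector()) <= tol))


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    ax, ay, az = (math.radians(a) for a in (rx, ry, rz))
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _voxel_affine(t: RigidTransform, geometry: VolumeGeometry, shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-space matrix/offset mapping output voxel -> input voxel.

    The physical-space map is x' = R (x - c) + c + t about the centre c;
    ndimage.affine_transform pulls input coordinates from output ones, so we
    pass the inverse map expressed in voxel units.
    """
    S = np.diag(geometry.voxel_size_mm)
    Sinv = np.diag(1.0 / np.asarray(geometry.voxel_size_mm))
    R = _rotation_matrix(t.rx, t.ry, t.rz)
    c_vox = (np.asarray(shape[:3]) - 1) / 2.0
    c_mm = S @ c_vox
    tvec = np.array([t.tx, t.ty, t.tz])
    # inverse physical map: x = R^T (x' - c - t) + c
    M = Sinv @ R.T @ S
    offset = Sinv @ (R.T @ (-c_mm - tvec)) + Sinv @ c_mm
    return M, offset


def apply_rigid(
    volume: np.ndarray,
    transform: RigidTransform,
    geometry: VolumeGeometry,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample a 3D volume under a rigid transform (pull interpolation).

    ``order=1`` for intensity images, ``order=0`` (nearest) for masks.  The
    identity transform returns a bit-identical copy.
    """
    if transform.is_identity():
        return volume.copy()
    M, offset = _voxel_affine(transform, geometry, volume.shape)
    return ndimage.affine_transform(
        volume.astype(np.float64), M, offset=offset, order=order, cval=cval, mode="constant"
    )


def _ssd(
    params: np.ndarray,
    moving: np.ndarray,
    fixed: np.ndarray,
    geometry: VolumeGeometry,
    order: int = 3,
) -> float:
    """Mean squared intensity difference over the valid overlap.

    Voxels pulled from outside the moving volume are excluded (a ones-mask
    is resampled alongside), so border padding does not dominate the cost;
    the mean (not the sum) keeps the criterion comparable across overlaps.
    Cubic interpolation inside the cost avoids the sub-degree bias linear
    interpolation introduces near the optimum; the final resampling of the
    data stays linear.
    """
    t = RigidTransform.from_vector(params)
    resampled = apply_rigid(moving, t, geometry, order=order)
    inside = apply_rigid(np.ones_like(moving), t, geometry, order=1) > 0.999
    n = int(inside.sum())
    if n < 0.25 * fixed.size:  # degenerate overlap
        return float(np.mean((moving - fixed) ** 2) * 1e6)
    return float(np.mean((resampled[inside] - fixed[inside]) ** 2))


def estimate_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    geometry: VolumeGeometry,
    xtol: float = 1e-5,
) -> tuple[RigidTransform, bool]:
    """Least-squares rigid registration of ``moving`` onto ``fixed``.

    Returns the transform and a convergence flag.  A frame already matching
    the reference (SSD below numerical noise) is returned as identity
    without optimisation.
    """
    scale = float(np.mean(np.abs(fixed))) or 1.0
    if _ssd(np.zeros(6), moving, fixed, geometry) <= (1e-9 * scale) ** 2:
        return RigidTransform.identity(), True
    res = optimize.minimize(
        _ssd,
        np.zeros(6),
        args=(moving, fixed, geometry),
        method="Powell",
        options={"xtol": xtol, "ftol": 1e-10, "maxiter": 3000},
    )
    return RigidTransform.from_vector(res.x), bool(res.success)


def realign_series(
    series: ASLSeries,
    reference_index: int = 0,
) -> tuple[ASLSeries, np.ndarray]:
    """Realign every frame to the reference frame (the first scan by default).

    Returns the resampled series and a (n_frames, 6) motion-parameter array
    (tx, ty, tz in mm; rx, ry, rz in degrees).  A frame whose registration
    fails to converge is flagged with a warning and retained unresampled.
    """
    if series.n_frames < 2:
        raise ValueError("realignment needs at least 2 frames")
    fixed = series.data[..., reference_index]
    out = np.empty_like(series.data, dtype=np.float64)
    motion = np.zeros((series.n_frames, 6))
    for i in range(series.n_frames):
        if i == reference_index:
            out[..., i] = fixed
            continue
        t, ok = estimate_rigid(series.data[..., i], fixed, series.geometry)
        if not ok:
            logger.warning("realignment of frame %d did not converge; frame retained as-is", i)
            out[..., i] = series.data[..., i]
            continue
        motion[i] = t.as_vector()
        out[..., i] = apply_rigid(series.data[..., i], t, series.geometry, order=1)
    realigned = ASLSeries(
        data=out,
        geometry=series.geometry,
        frame_labels=list(series.frame_labels) if series.frame_labels else None,
        conditions=list(series.conditions) if series.conditions else None,
    )
    return realigned, motion
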