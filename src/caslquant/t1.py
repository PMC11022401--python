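"""Voxelwise T1 fitting from inversion-recovery series.

The three-parameter relaxation model S(TI) = A + B exp(-TI/T1) is fitted
per voxel by nonlinear least squares.  The implementation exploits the
model's partial linearity: for any fixed T1 the optimal (A, B) solve a
linear system, so a dense T1 grid search (which doubles as the multi-start
initialisation) locates the global basin and a full 3-parameter
Levenberg-Marquardt refinement polishes it.  Voxels whose refined T1 falls
outside the physiological window (50, 10000) ms, or whose signal carries no
recovery information (B ~ 0), are masked invalid rather than silently
zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .geometry import VolumeGeometry
from .io import ASLSeries, QuantMap
from .realign import RigidTransform, apply_rigid


@dataclass
class T1FitOptions:
    """Tunable fit settings.

    ``t1_grid`` seeds the multi-start search (ms); a dense log-spaced grid
    is added around it.  ``t1_bounds`` is the open validity window (ms).
    ``xtol`` is the relative convergence tolerance of the refinement.
    ``magnitude`` flags magnitude-reconstructed input, which is passed
    through polarity restoration first.
    """

    t1_grid: tuple[float, ...] = (300.0, 800.0, 1500.0, 3000.0)
    t1_bounds: tuple[float, float] = (50.0, 10000.0)
    xtol: float = 1e-8
    grid_points: int = 96
    magnitude: bool = False


@dataclass
class T1FitResult:
    """Voxelwise fit maps; invalid voxels are masked, never silently zero."""

    t1: np.ndarray
    a: np.ndarray
    b: np.ndarray
    residual: np.ndarray
    mask: np.ndarray
    geometry: VolumeGeometry | None = None
    ti_list: np.ndarray = field(default_factory=lambda: np.array([]))

    def t1_quantmap(self) -> QuantMap:
        if self.geometry is None:
            raise ValueError("fit result carries no geometry")
        return QuantMap(data=self.t1, geometry=self.geometry, mask=self.mask)


def _model(ti: np.ndarray, a: float, b: float, t1: float) -> np.ndarray:
    return a + b * np.exp(-ti / t1)


def restore_polarity(series: np.ndarray, ti_list: "np.ndarray | list[float]") -> np.ndarray:
    """Restore signs of a magnitude inversion-recovery series.

    Signed input (contains negatives) is returned unchanged.  For magnitude
    input, samples before the minimum-signal inversion time are flipped
    negative (the minimum-signal heuristic for the zero crossing); the
    sample at the minimum itself keeps whichever sign gives the smaller
    magnitude discontinuity, which for a clean recovery is negative.  A
    monotone series (minimum at the first sample) is returned unchanged.
    """
    ti = np.asarray(ti_list, dtype=np.float64)
    s = np.asarray(series, dtype=np.float64)
    if s.shape[-1] != ti.size:
        raise ValueError("series frame count must match TI count")
    if (s < 0).any():
        return s.copy()
    out = s.copy()
    idx_min = np.argmin(s, axis=-1)
    ti_idx = np.arange(ti.size)
    flip = ti_idx < idx_min[..., None]
    out[flip] = -out[flip]
    return out


def fit_t1(
    ir_series: "ASLSeries | np.ndarray",
    ti_list: "np.ndarray | list[float]",
    options: T1FitOptions | None = None,
) -> T1FitResult:
    """Fit S(TI) = A + B exp(-TI/T1) per voxel.

    Accepts an :class:`~caslquant.io.ASLSeries` (one frame per TI) or a bare
    array with TI on the last axis.  Requires at least 3 distinct inversion
    times.  The fit is scale-equivariant: scaling the series by c scales A
    and B by c and leaves T1 unchanged.
    """
    options = options or T1FitOptions()
    geometry = None
    if isinstance(ir_series, ASLSeries):
        geometry = ir_series.geometry
        data = ir_series.data
    else:
        data = np.asarray(ir_series, dtype=np.float64)
    ti = np.asarray(ti_list, dtype=np.float64)
    if np.unique(ti).size < 3:
        raise ValueError("need at least 3 distinct inversion times")
    if data.shape[-1] != ti.size:
        raise ValueError(
            f"series has {data.shape[-1]} frames but {ti.size} inversion times"
        )
    if options.magnitude:
        data = restore_polarity(data, ti)
    spatial = data.shape[:-1]
    Y = data.reshape(-1, ti.size)
    nv = Y.shape[0]

    lo, hi = options.t1_bounds
    grid = np.unique(
        np.concatenate(
            [
                np.asarray(options.t1_grid, dtype=np.float64),
                np.geomspace(lo * 1.2, hi * 0.9, options.grid_points),
            ]
        )
    )

    # identifiability: a flat series carries no T1 information
    scale = np.abs(Y).max(axis=1)
    flat = np.ptp(Y, axis=1) <= 1e-12 * np.maximum(scale, 1.0)

    best_cost = np.full(nv, np.inf)
    best_t1 = np.full(nv, np.nan)
    best_ab = np.zeros((nv, 2))
    for t1c in grid:
        X = np.column_stack([np.ones_like(ti), np.exp(-ti / t1c)])
        pinv = np.linalg.pinv(X)
        coef = Y @ pinv.T  # (nv, 2)
        resid = Y - coef @ X.T
        cost = np.einsum("ij,ij->i", resid, resid)
        better = cost < best_cost
        best_cost[better] = cost[better]
        best_t1[better] = t1c
        best_ab[better] = coef[better]

    t1_out = np.full(nv, np.nan)
    a_out = np.full(nv, np.nan)
    b_out = np.full(nv, np.nan)
    res_out = np.full(nv, np.nan)
    valid = np.zeros(nv, dtype=bool)

    for v in range(nv):
        if flat[v] or not np.isfinite(best_t1[v]):
            continue
        x0 = np.array([best_ab[v, 0], best_ab[v, 1], best_t1[v]])
        try:
            sol = optimize.least_squares(
                lambda p: _model(ti, *p) - Y[v],
                x0,
                bounds=([-np.inf, -np.inf, lo], [np.inf, np.inf, hi]),
                xtol=options.xtol,
                method="trf",
            )
        except Exception:
            continue
        cost = 2.0 * sol.cost
        if cost <= best_cost[v] + 1e-12 * max(best_cost[v], 1.0):
            a, b, t1v = sol.x
        else:  # refinement should never worsen the grid optimum
            a, b, t1v = x0
            cost = best_cost[v]
        amp = max(abs(a), scale[v], 1.0)
        if not (lo < t1v < hi) or abs(b) <= 1e-9 * amp:
            continue
        t1_out[v], a_out[v], b_out[v] = t1v, a, b
        res_out[v] = np.sqrt(cost / ti.size)
        valid[v] = True

    return T1FitResult(
        t1=t1_out.reshape(spatial),
        a=a_out.reshape(spatial),
        b=b_out.reshape(spatial),
        residual=res_out.reshape(spatial),
        mask=valid.reshape(spatial),
        geometry=geometry,
        ti_list=ti,
    )


def resample_t1_to_asl(
    t1_result: T1FitResult,
    transform: RigidTransform,
    geometry: VolumeGeometry | None = None,
) -> T1FitResult:
    """Carry a fitted T1 map into the ASL frame under a rigid transform.

    The transform is the one estimated by co-registering the long-TI IR
    image to the mean ASL image.  Scalar maps are resampled with linear
    interpolation, the validity mask with nearest-neighbour so it stays
    binary.
    """
    geometry = geometry or t1_result.geometry
    if geometry is None:
        raise ValueError("no geometry available for resampling")
    if t1_result.t1.shape != geometry.shape:
        raise ValueError("fit-result shape does not match the target geometry")
    lin = lambda m: apply_rigid(np.nan_to_num(m), transform, geometry, order=1)
    mask = apply_rigid(t1_result.mask.astype(np.float64), transform, geometry, order=0) > 0.5
    return T1FitResult(
        t1=lin(t1_result.t1),
        a=lin(t1_result.a),
        b=lin(t1_result.b),
        residual=lin(t1_result.residual),
        mask=mask,
        geometry=geometry,
        ti_list=t1_result.ti_list,
    )
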