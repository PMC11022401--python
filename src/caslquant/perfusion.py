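"""Absolute CBF quantification for pseudo-continuous ASL.

The chain implemented here turns a realigned, interleaved control/label
series plus a tissue T1 map and a labelling efficiency into absolute
cerebral blood flow (CBF) maps:

1. surround subtraction pairs each label frame with the mean of its
   flanking control frames, suppressing slow signal drifts;
2. the one-compartment kinetic model (Buxton) inverts the perfusion-weighted
   difference signal DeltaS into CBF::

       CBF = 6000 * lambda * DeltaS * exp(PLD_eff / T1_blood)
             / (2 * alpha * T1' * S_control * (1 - exp(-tau / T1')))

   with all times in seconds inside the expression, lambda the blood-brain
   partition coefficient (ml/g), alpha the labelling efficiency, tau the
   labelling duration, T1' the fitted tissue T1 and T1_blood the arterial
   blood T1.  The factor 6000 converts ml/g/s to the conventional
   ml/100g/min;
3. the post-labelling delay is slice-specific in a multi-slice readout: the
   dead time after labelling is divided equally over slices, and a fixed
   fat-suppression gradient adds 7 ms before the first slice::

       PLD_eff(slice) = PLD + offset + (slice - 1) * (TR - tau - PLD) / n_slices

   with 1-based slice numbers in acquisition order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .geometry import VolumeGeometry
from .io import ASLSeries, QuantMap

#: ml/g/s -> ml/100 g/min
CBF_UNIT_FACTOR = 6000.0


@dataclass(frozen=True)
class AcquisitionParams:
    """Scalar constants of the CBF equation and the slice timing.

    All times in milliseconds.  Defaults are the 7 T mouse protocol values:
    labelling duration 3000 ms, nominal PLD 200 ms, TR 3450 ms, 5 slices,
    blood-brain partition coefficient 0.89 ml/g, arterial blood T1 1700 ms,
    and a 7 ms fat-suppression offset added to the first slice's delay.
    The labelling efficiency ``alpha`` has no physical default: it is
    measured per session and must be set explicitly.
    """

    tau: float = 3000.0
    pld: float = 200.0
    tr: float = 3450.0
    n_slices: int = 5
    lambda_bbp: float = 0.89
    t1_blood: float = 1700.0
    alpha: float | None = None
    fat_suppression_offset: float = 7.0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.pld <= 0 or self.tr <= 0 or self.t1_blood <= 0:
            raise ValueError("all times must be positive")
        if self.tau + self.pld >= self.tr:
            raise ValueError("tau + pld must be smaller than tr")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.lambda_bbp <= 0:
            raise ValueError("lambda_bbp must be positive")
        if self.alpha is not None and not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")

    def with_alpha(self, alpha: float) -> "AcquisitionParams":
        return replace(self, alpha=alpha)


def effective_pld(params: AcquisitionParams, slice_number: int) -> float:
    """Slice-specific effective post-labelling delay in ms.

    ``slice_number`` is 1-based in acquisition order.  The readout dead time
    ``TR - tau - PLD`` is divided equally over slices, and the
    fat-suppression offset (7 ms by default) shifts every slice's delay.
    """
    if not 1 <= slice_number <= params.n_slices:
        raise ValueError(
            f"slice_number {slice_number} out of range 1..{params.n_slices}"
        )
    gap = (params.tr - params.tau - params.pld) / params.n_slices
    return params.pld + params.fat_suppression_offset + (slice_number - 1) * gap


@dataclass
class DeltaSSeries:
    """Per-repetition perfusion-weighted difference maps.

    ``delta_s`` and ``s_control`` have axis order (x, y, slice, repetition);
    one repetition per label frame.  ``conditions`` annotates repetitions.
    """

    delta_s: np.ndarray
    s_control: np.ndarray
    geometry: VolumeGeometry
    conditions: list[str]

    def __post_init__(self) -> None:
        if self.delta_s.shape != self.s_control.shape:
            raise ValueError("delta_s and s_control shapes must match")
        if len(self.conditions) != self.delta_s.shape[3]:
            raise ValueError("conditions length must match repetition count")

    @property
    def n_repetitions(self) -> int:
        return self.delta_s.shape[3]


def surround_subtract(series: ASLSeries) -> DeltaSSeries:
    """Surround subtraction of an interleaved control/label series.

    Each label frame is paired with the mean of its flanking control frames:
    DeltaS_i = mean(control_before, control_after) - label_i, and S_control_i
    is that same mean.  A label frame at either end of the series, with only
    one neighbouring control, uses that single control.
    """
    labels = series.frame_labels
    if labels is None:
        raise ValueError("series carries no control/label annotation")
    for i in range(len(labels) - 1):
        if labels[i] == labels[i + 1]:
            raise ValueError("series is not strictly alternating control/label")
    label_idx = [i for i, l in enumerate(labels) if l == "label"]
    if not label_idx:
        raise ValueError("series contains no label frames")
    data = series.data
    n = data.shape[3]
    ds = np.empty(data.shape[:3] + (len(label_idx),), dtype=np.float64)
    sc = np.empty_like(ds)
    conds = []
    for k, i in enumerate(label_idx):
        flank = [j for j in (i - 1, i + 1) if 0 <= j < n]
        ctrl = data[..., flank].mean(axis=3)
        ds[..., k] = ctrl - data[..., i]
        sc[..., k] = ctrl
        conds.append(series.conditions[i] if series.conditions is not None else "baseline")
    return DeltaSSeries(delta_s=ds, s_control=sc, geometry=series.geometry, conditions=conds)


def buxton_delta_s(
    cbf: np.ndarray | float,
    s_control: np.ndarray | float,
    t1_tissue: np.ndarray | float,
    pld_eff_ms: float,
    params: AcquisitionParams,
) -> np.ndarray | float:
    """Forward one-compartment model: perfusion-weighted signal DeltaS.

    ``cbf`` in ml/100g/min, ``t1_tissue`` in ms.  This is the exact inverse
    of :func:`quantify_cbf`'s voxelwise expression and is shared with the
    synthetic forward simulator.
    """
    if params.alpha is None:
        raise ValueError("labelling efficiency alpha is not set")
    f = np.asarray(cbf, dtype=np.float64) / CBF_UNIT_FACTOR  # ml/g/s
    t1p = np.asarray(t1_tissue, dtype=np.float64) / 1000.0  # s
    tau = params.tau / 1000.0
    pld = pld_eff_ms / 1000.0
    t1b = params.t1_blood / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ds = (
            f
            / params.lambda_bbp
            * 2.0
            * params.alpha
            * t1p
            * np.asarray(s_control, dtype=np.float64)
            * (1.0 - np.exp(-tau / np.where(t1p > 0, t1p, np.inf)))
            * math.exp(-pld / t1b)
        )
    return ds


def quantify_cbf(
    dss: DeltaSSeries,
    t1_map: QuantMap,
    params: AcquisitionParams,
    slice_order: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-repetition absolute CBF maps (ml/100g/min) via the Buxton model.

    Parameters
    ----------
    dss : surround-subtracted difference series in the ASL frame.
    t1_map : fitted tissue T1 (ms) resampled to the ASL frame; its validity
        mask gates the output.
    params : acquisition constants; ``alpha`` must be set.
    slice_order : optional mapping array index -> acquisition slice number
        (1-based).  Default: slices acquired in array order.

    Returns
    -------
    cbf : array (x, y, slice, repetition).
    mask : valid-voxel mask (invalid T1 or non-positive S_control masked).
    """
    if params.alpha is None:
        raise ValueError("labelling efficiency alpha is not set")
    if t1_map.data.shape != dss.delta_s.shape[:3]:
        raise ValueError("T1 map geometry does not match the DeltaS series")
    nz = dss.delta_s.shape[2]
    if slice_order is None:
        slice_order = np.arange(1, nz + 1)
    t1p = t1_map.data / 1000.0  # s
    tau = params.tau / 1000.0
    t1b = params.t1_blood / 1000.0
    valid = t1_map.mask & (t1p > 0)
    mask = valid[..., None] & (dss.s_control > 0)
    if not mask.any():
        raise ValueError("no valid voxels: check T1 map and S_control")
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (
            2.0
            * params.alpha
            * t1p
            * (1.0 - np.exp(-tau / np.where(t1p > 0, t1p, np.inf)))
        )
        cbf = np.zeros_like(dss.delta_s)
        for z in range(nz):
            pld = effective_pld(params, int(slice_order[z])) / 1000.0
            cbf[:, :, z, :] = (
                CBF_UNIT_FACTOR
                * params.lambda_bbp
                * dss.delta_s[:, :, z, :]
                * math.exp(pld / t1b)
                / (denom[:, :, z, None] * dss.s_control[:, :, z, :])
            )
    cbf[~mask] = 0.0
    return cbf, mask


def estimate_labelling_efficiency(
    control_img: np.ndarray,
    label_img: np.ndarray,
    vessel_mask: np.ndarray,
) -> tuple[float, dict]:
    """Labelling efficiency from a downstream label/control vessel scan.

    alpha is estimated per voxel as (control - label) / (2 * control) inside
    the vessel mask, averaged, and clipped to (0, 1].  Full inversion gives
    label = -control hence alpha = 1; no inversion gives alpha = 0.

    Returns the scalar alpha and a diagnostics dict with the per-voxel
    values and their dispersion.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any():
        raise ValueError("vessel mask is empty")
    c = np.asarray(control_img, dtype=np.float64)[vessel_mask]
    l = np.asarray(label_img, dtype=np.float64)[vessel_mask]
    if c.mean() <= 0:
        raise ValueError("mean control signal in the vessel mask is not positive")
    per_voxel = (c - l) / (2.0 * c)
    alpha = float(np.clip(per_voxel.mean(), np.finfo(float).tiny, 1.0))
    info = {
        "per_voxel": per_voxel,
        "std": float(per_voxel.std(ddof=1)) if per_voxel.size > 1 else 0.0,
        "n_voxels": int(per_voxel.size),
    }
    return alpha, info


def smooth_map(
    qmap: QuantMap,
    fwhm_xy: tuple[float, float] | None = None,
) -> QuantMap:
    """In-plane Gaussian smoothing, mask-aware.

    ``fwhm_xy`` in micrometres per in-plane axis; default twice the voxel
    size.  sigma = FWHM / (2 sqrt(2 ln 2)).  No through-slice smoothing.
    Mask-aware normalisation (smoothing x*m and m separately and dividing)
    keeps voxels at the mask edge from being dragged toward zero.
    """
    dx, dy = qmap.geometry.voxel_size_xy
    if fwhm_xy is None:
        fwhm_xy = (2.0 * dx, 2.0 * dy)
    if fwhm_xy[0] <= 0 or fwhm_xy[1] <= 0:
        raise ValueError("FWHM must be positive")
    k = 2.0 * math.sqrt(2.0 * math.log(2.0))
    sigma_px = (fwhm_xy[0] / k / dx, fwhm_xy[1] / k / dy)
    m = qmap.mask.astype(np.float64)
    num = np.empty_like(qmap.data, dtype=np.float64)
    den = np.empty_like(num)
    # periodic boundary keeps the normalised kernel mass exact (mean-
    # preserving); the in-plane borders of an ASL FOV are background and the
    # real edge handling is done by the mask normalisation below
    for z in range(qmap.data.shape[2]):
        num[:, :, z] = ndimage.gaussian_filter(qmap.data[:, :, z] * m[:, :, z], sigma_px, mode="wrap")
        den[:, :, z] = ndimage.gaussian_filter(m[:, :, z], sigma_px, mode="wrap")
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 1e-12)
    out[~qmap.mask] = 0.0
    return QuantMap(data=out, geometry=qmap.geometry, mask=qmap.mask.copy())


def condition_mean(
    cbf_reps: np.ndarray,
    conditions: list[str],
) -> dict[str, tuple[np.ndarray, int]]:
    """Voxelwise mean CBF per condition with repetition counts.

    ``cbf_reps`` has axis order (x, y, slice, repetition).  Raises on a
    condition annotation with zero repetitions.
    """
    if len(conditions) != cbf_reps.shape[3]:
        raise ValueError("conditions length must match repetition count")
    out: dict[str, tuple[np.ndarray, int]] = {}
    for cond in dict.fromkeys(conditions):  # preserve first-seen order
        idx = [i for i, c in enumerate(conditions) if c == cond]
        if not idx:
            raise ValueError(f"condition {cond!r} has zero repetitions")
        out[cond] = (cbf_reps[..., idx].mean(axis=3), len(idx))
    return out
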