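"""Cerebrovascular reactivity from baseline and hypercapnic CBF maps.

CVR is the fractional perfusion response to a vasodilatory CO2 challenge,

    %dCBF = (CBF_challenge - CBF_baseline) / CBF_baseline * 100,

computed voxelwise.  Voxels with baseline CBF below a safety floor are
masked rather than allowed to blow up the ratio; the floor default of
5 ml/100g/min sits well below any perfused tissue.  Because CVR is a ratio
of two CBF maps, any common multiplicative miscalibration (for instance a
wrong global labelling efficiency) cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import QuantMap
from .perfusion import AcquisitionParams, condition_mean, quantify_cbf, smooth_map, surround_subtract
from .realign import realign_series
from .synthetic import EffectSpec, Phantom, forward_asl

DEFAULT_BASELINE_FLOOR = 5.0  # ml/100g/min


@dataclass
class CVRMap:
    """Percent CBF change map with its validity mask and the floor used."""

    data: np.ndarray
    mask: np.ndarray
    baseline_floor: float

    def as_quantmap(self, geometry) -> QuantMap:
        return QuantMap(data=self.data, geometry=geometry, mask=self.mask)


def compute_cvr(
    cbf_baseline: QuantMap,
    cbf_challenge: QuantMap,
    baseline_floor: float = DEFAULT_BASELINE_FLOOR,
) -> CVRMap:
    """Voxelwise %dCBF between challenge and baseline CBF maps."""
    if cbf_baseline.data.shape != cbf_challenge.data.shape:
        raise ValueError("baseline and challenge maps have different shapes")
    if cbf_baseline.geometry != cbf_challenge.geometry:
        raise ValueError("baseline and challenge maps have different geometry")
    base = cbf_baseline.data
    chal = cbf_challenge.data
    mask = cbf_baseline.mask & cbf_challenge.mask & (base >= baseline_floor)
    out = np.zeros_like(base, dtype=np.float64)
    np.divide(chal - base, base, out=out, where=mask)
    out *= 100.0
    out[~mask] = 0.0
    return CVRMap(data=out, mask=mask, baseline_floor=baseline_floor)


def cvr_recovery_check(
    phantom: Phantom,
    params: AcquisitionParams,
    effect: EffectSpec,
    n_pairs: int = 60,
    seed: int = 0,
    realign: bool = False,
    smooth: bool = True,
    baseline_floor: float = DEFAULT_BASELINE_FLOOR,
) -> dict:
    """End-to-end validation: simulate both conditions, quantify, map CVR.

    Runs the forward simulator for baseline and challenge, pushes both
    series through surround subtraction, Buxton quantification,
    per-condition averaging and in-plane smoothing (FWHM twice the voxel
    size, as in the quantification chain proper), and compares regional
    mean CVR against the ground truth 100*(challenge_factor - 1).
    Smoothing before the ratio suppresses the voxel-level noise that would
    otherwise bias the voxelwise ratio upward (Jensen effect of a noisy
    denominator); because the challenge scales CBF multiplicatively
    everywhere, smoothing is transparent to the noise-free CVR value.
    Realignment is opt-in: the simulator injects no motion, so it is
    exercised by its own tests rather than burned into every recovery run.

    Returns a report dict with ground truth, per-region recovered CVR and
    recovered per-condition CBF.
    """
    t1_map = QuantMap(data=phantom.t1_map, geometry=phantom.geometry, mask=phantom.brain_mask)
    cond_maps = {}
    for i, condition in enumerate(("baseline", "challenge")):
        series = forward_asl(
            phantom, params, effect=effect, condition=condition,
            n_pairs=n_pairs, seed=seed + i,
        )
        if realign:
            series, _ = realign_series(series)
        dss = surround_subtract(series)
        cbf_reps, mask = quantify_cbf(dss, t1_map, params)
        mean_map = condition_mean(cbf_reps, dss.conditions)[condition][0]
        if smooth:
            qm = QuantMap(data=mean_map, geometry=phantom.geometry, mask=phantom.brain_mask)
            mean_map = smooth_map(qm).data
        cond_maps[condition] = mean_map
    geometry = phantom.geometry
    base = QuantMap(data=cond_maps["baseline"], geometry=geometry, mask=phantom.brain_mask)
    chal = QuantMap(data=cond_maps["challenge"], geometry=geometry, mask=phantom.brain_mask)
    cvr = compute_cvr(base, chal, baseline_floor=baseline_floor)
    truth = 100.0 * (effect.challenge_factor - 1.0)
    regions = {}
    for r in range(1, phantom.n_regions + 1):
        sel = (phantom.labels == r) & cvr.mask
        regions[r] = {
            "cvr_mean": float(cvr.data[sel].mean()) if sel.any() else np.nan,
            "cbf_baseline_mean": float(cond_maps["baseline"][sel].mean()) if sel.any() else np.nan,
            "cbf_challenge_mean": float(cond_maps["challenge"][sel].mean()) if sel.any() else np.nan,
            "n_voxels": int(sel.sum()),
        }
    return {
        "ground_truth_cvr": truth,
        "challenge_factor": effect.challenge_factor,
        "regions": regions,
        "cvr_map": cvr,
        "max_regional_error": max(
            abs(v["cvr_mean"] - truth) for v in regions.values() if np.isfinite(v["cvr_mean"])
        ),
    }
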