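"""Ground-truth generators for every acquisition the pipeline consumes.

The module emulates, with known ground truth, (a) interleaved control/label
pCASL series whose difference signal follows the one-compartment kinetic
model for a chosen CBF map, under baseline and hypercapnic-challenge
conditions, (b) inversion-recovery series for T1 mapping, (c) the
downstream label/control scan used to measure the labelling efficiency,
and (d) 2D fluorescence-style vessel images with known tube geometry.
Every generator is deterministic given its seed.

Noise is additive Gaussian, independent across frames and voxels, with a
per-voxel standard deviation expressed as a fraction of the equilibrium
signal M0; no physiological drift is simulated (a drift hook is a listed
extension).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import VolumeGeometry
from .io import ASLSeries
from .perfusion import AcquisitionParams, buxton_delta_s, effective_pld


@dataclass
class Phantom:
    """Region-labelled digital phantom with per-region tissue parameters.

    ``labels`` is a 3D integer map with 0 = background and region labels
    contiguous from 1.  ``cbf`` (ml/100g/min), ``t1`` (ms) and ``m0``
    (arbitrary signal units) are arrays of length ``n_regions + 1`` indexed
    by label; row 0 is the background (CBF 0, M0 0).
    """

    labels: np.ndarray
    cbf: np.ndarray
    t1: np.ndarray
    m0: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        for name in ("cbf", "t1", "m0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = int(self.labels.max())
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(present.size)) or present[0] != 0:
            raise ValueError("labels must be contiguous integers starting at 0")
        if len(self.cbf) != n + 1 or len(self.t1) != n + 1 or len(self.m0) != n + 1:
            raise ValueError("per-region value arrays must have length n_regions + 1")
        if (self.cbf < 0).any():
            raise ValueError("CBF must be non-negative")
        if (self.t1[1:] <= 0).any():
            raise ValueError("tissue T1 must be positive")
        if (self.m0[1:] <= 0).any():
            raise ValueError("M0 must be positive inside the brain")

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def cbf_map(self) -> np.ndarray:
        return self.cbf[self.labels]

    @property
    def t1_map(self) -> np.ndarray:
        return self.t1[self.labels]

    @property
    def m0_map(self) -> np.ndarray:
        return self.m0[self.labels]


@dataclass
class EffectSpec:
    """Group/condition contrasts injected into the simulator.

    ``genotype_factor`` multiplies CBF everywhere (or per region when an
    array of length n_regions is given); ``challenge_factor`` multiplies CBF
    under the CO2 challenge, so ground-truth CVR is 100*(factor - 1) percent.
    ``noise_sigma`` is the Gaussian noise SD as a fraction of M0.
    """

    genotype_factor: float | np.ndarray = 1.0
    challenge_factor: float = 1.0
    noise_sigma: float = 0.0
    n_subjects: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.genotype_factor) <= 0) or self.challenge_factor <= 0:
            raise ValueError("effect factors must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def make_phantom(
    geometry: VolumeGeometry,
    n_regions: int,
    region_values: dict[str, "np.ndarray | list[float]"],
    seed: int = 0,
) -> Phantom:
    """Deterministic nested-rectangle phantom with stated per-region values.

    Regions are concentric rectangular shells inside a brain footprint with
    a 2-voxel background margin, identical across slices — a crude but fully
    controlled stand-in for a parcellated brain.  ``region_values`` must
    supply ``cbf``, ``t1`` and ``m0`` sequences of length ``n_regions``.
    ``seed`` is accepted for interface uniformity; the label map itself is
    deterministic.
    """
    nx, ny = geometry.matrix
    margin = 2
    inner_x, inner_y = nx - 2 * margin, ny - 2 * margin
    if n_regions < 1:
        raise ValueError("need at least one region")
    if min(inner_x, inner_y) - 2 * (n_regions - 1) < 2:
        raise ValueError(
            f"{n_regions} nested regions do not fit a {nx}x{ny} matrix"
        )
    for key in ("cbf", "t1", "m0"):
        if key not in region_values or len(region_values[key]) != n_regions:
            raise ValueError(f"region_values[{key!r}] must have length {n_regions}")
    labels2d = np.zeros((nx, ny), dtype=np.int32)
    for r in range(n_regions):
        x0, y0 = margin + r, margin + r
        x1, y1 = nx - margin - r, ny - margin - r
        labels2d[x0:x1, y0:y1] = r + 1
    labels = np.repeat(labels2d[:, :, None], geometry.n_slices, axis=2)
    pad = lambda v, bg: np.concatenate([[bg], np.asarray(v, dtype=np.float64)])
    return Phantom(
        labels=labels,
        cbf=pad(region_values["cbf"], 0.0),
        t1=pad(region_values["t1"], 1.0),
        m0=pad(region_values["m0"], 0.0),
        geometry=geometry,
    )


#: per-region defaults mimicking a 12-ROI mouse parcellation (cortex,
#: striatum, thalamus, pallidum ...): CBF spread over the physiological
#: range, grey-matter T1 near 1700-1900 ms at 7 T, uniform M0.
DEFAULT_REGION_VALUES = {
    "cbf": [250.0, 230.0, 210.0, 190.0, 170.0, 150.0, 130.0, 110.0, 90.0, 70.0, 50.0, 30.0],
    "t1": [1700.0, 1750.0, 1800.0, 1700.0, 1850.0, 1750.0, 1900.0, 1800.0, 1700.0, 1750.0, 1850.0, 1800.0],
    "m0": [1000.0] * 12,
}


def default_phantom(geometry: VolumeGeometry | None = None) -> Phantom:
    """A 12-region phantom spanning CBF 30-250 ml/100g/min."""
    if geometry is None:
        geometry = VolumeGeometry(
            voxel_size_xy=(260.0, 400.0), slice_thickness=800.0, n_slices=5, matrix=(32, 32)
        )
    return make_phantom(geometry, 12, DEFAULT_REGION_VALUES)


def _effective_cbf(phantom: Phantom, effect: EffectSpec | None, condition: str) -> np.ndarray:
    cbf = phantom.cbf.copy()
    if effect is not None:
        g = np.asarray(effect.genotype_factor, dtype=np.float64)
        if g.ndim == 0:
            cbf[1:] *= float(g)
        else:
            if g.size != phantom.n_regions:
                raise ValueError("per-region genotype factor length mismatch")
            cbf[1:] *= g
        if condition == "challenge":
            cbf[1:] *= effect.challenge_factor
    return cbf


def forward_asl(
    phantom: Phantom,
    params: AcquisitionParams,
    effect: EffectSpec | None = None,
    condition: str = "baseline",
    n_pairs: int = 60,
    seed: int = 0,
    label_first: bool = False,
) -> ASLSeries:
    """Simulate an interleaved control/label pCASL series.

    Control frames are M0 plus noise; label frames are M0 - DeltaS plus
    noise, with DeltaS from the one-compartment model evaluated with each
    slice's effective PLD.  Under ``condition="challenge"`` the phantom CBF
    is multiplied by the effect's challenge factor.  The default 60 pairs
    reproduce the 120-frame (60/60 control/label) resting-state protocol.
    """
    if condition not in ("baseline", "challenge"):
        raise ValueError("condition must be 'baseline' or 'challenge'")
    if params.alpha is None:
        raise ValueError("labelling efficiency alpha is not set")
    cbf = _effective_cbf(phantom, effect, condition)
    cbf_map = cbf[phantom.labels]
    m0 = phantom.m0_map
    t1 = phantom.t1_map
    nz = phantom.geometry.n_slices
    delta_s = np.zeros_like(m0)
    for z in range(nz):
        delta_s[:, :, z] = buxton_delta_s(
            cbf_map[:, :, z], m0[:, :, z], t1[:, :, z], effective_pld(params, z + 1), params
        )
    rng = np.random.default_rng(seed)
    sigma = (effect.noise_sigma if effect is not None else 0.0) * m0
    n_frames = 2 * n_pairs
    data = np.empty(m0.shape + (n_frames,), dtype=np.float64)
    control_parity = 1 if label_first else 0
    for i in range(n_frames):
        clean = m0 if i % 2 == control_parity else m0 - delta_s
        data[..., i] = clean + rng.standard_normal(m0.shape) * sigma
    labels = ["label" if (i % 2 != control_parity) else "control" for i in range(n_frames)]
    return ASLSeries(
        data=data,
        geometry=phantom.geometry,
        frame_labels=labels,
        conditions=[condition] * n_frames,
    )


def forward_ir(
    phantom: Phantom,
    ti_list: "np.ndarray | list[float]",
    noise_sigma: float = 0.0,
    seed: int = 0,
    magnitude: bool = False,
) -> ASLSeries:
    """Simulate a non-selective inversion-recovery series.

    Per voxel S(TI) = A + B exp(-TI/T1) with A = M0 and B = -2 M0 (perfect
    inversion), one frame per inversion time, plus Gaussian noise of SD
    ``noise_sigma * M0``.  ``magnitude=True`` returns |S| to exercise
    polarity restoration.
    """
    ti = np.asarray(ti_list, dtype=np.float64)
    if ti.size == 0:
        raise ValueError("ti_list is empty")
    if ti.size > 1 and not (np.diff(ti) > 0).all():
        raise ValueError("ti_list must be strictly increasing")
    if (ti <= 0).any():
        raise ValueError("inversion times must be positive")
    m0 = phantom.m0_map
    t1 = np.where(phantom.t1_map > 0, phantom.t1_map, np.inf)
    rng = np.random.default_rng(seed)
    data = np.empty(m0.shape + (ti.size,), dtype=np.float64)
    for k, t in enumerate(ti):
        clean = m0 + (-2.0 * m0) * np.exp(-t / t1)
        data[..., k] = clean + rng.standard_normal(m0.shape) * noise_sigma * m0
    if magnitude:
        data = np.abs(data)
    return ASLSeries(data=data, geometry=phantom.geometry, frame_labels=None, conditions=None)


def forward_efficiency_pair(
    true_alpha: float,
    vessel_mask: np.ndarray,
    m0: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the downstream label/control labelling-efficiency scan.

    Inside the vessel mask the label signal is M0 (1 - 2 alpha) — full
    inversion (alpha = 1) flips the sign; outside, label equals control.
    Returns ``(control, label)`` images.
    """
    if not (0.0 < true_alpha <= 1.0):
        raise ValueError("true_alpha must lie in (0, 1]")
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any():
        raise ValueError("vessel mask is empty")
    rng = np.random.default_rng(seed)
    control = np.full(vessel_mask.shape, float(m0))
    label = control.copy()
    label[vessel_mask] = m0 * (1.0 - 2.0 * true_alpha)
    control = control + rng.standard_normal(vessel_mask.shape) * noise_sigma * m0
    label = label + rng.standard_normal(vessel_mask.shape) * noise_sigma * m0
    return control, label


# ---------------------------------------------------------------------------
# vessel-image generator


@dataclass
class VesselImageTruth:
    """A synthetic vessel image and its exact ground truth."""

    image: np.ndarray
    mask: np.ndarray
    tube_lengths_px: list[float]
    width_px: float
    tubes: list[np.ndarray] = field(default_factory=list)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())


def polyline_length(points: np.ndarray) -> float:
    """Euclidean length of a polyline given as an (n, 2) point array."""
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _min_distance_to_polyline(shape: tuple[int, int], points: np.ndarray) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    P = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
    d = np.full(P.shape[0], np.inf)
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) == 1:
        d = np.linalg.norm(P - pts[0], axis=1)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            proj = np.zeros(P.shape[0])
        else:
            proj = np.clip((P - a) @ ab / denom, 0.0, 1.0)
        closest = a + proj[:, None] * ab
        d = np.minimum(d, np.linalg.norm(P - closest, axis=1))
    return d.reshape(shape)


def random_tube_set(
    n_tubes: int,
    shape: tuple[int, int],
    width_px: float,
    seed: int = 0,
    margin: float = 15.0,
) -> list[np.ndarray]:
    """Non-intersecting straight tubes at a shared random orientation.

    Tubes run parallel (one random direction per call) at perpendicular
    offsets spaced at least four widths apart, so segmented components map
    one-to-one onto generated tubes.  Used by the morphometry validation
    suite.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    angle = rng.uniform(0, math.pi)
    d = np.array([math.cos(angle), math.sin(angle)])
    n = np.array([-d[1], d[0]])
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    max_off = 0.5 * min(h, w) - margin - width_px
    spacing = max(4.0 * width_px, 2.0 * max_off / max(n_tubes, 1))
    offsets = (np.arange(n_tubes) - (n_tubes - 1) / 2.0) * min(spacing, 2.0 * max_off / max(n_tubes - 1, 1) if n_tubes > 1 else spacing)
    tubes = []
    for off in offsets:
        centre = c + off * n
        # clip the segment to stay inside the margin box
        half = 0.5 * min(h, w) - margin
        jitter = rng.uniform(0.7, 1.0)
        a = centre - jitter * half * d
        b = centre + jitter * half * d
        a = np.clip(a, margin, [h - 1 - margin, w - 1 - margin])
        b = np.clip(b, margin, [h - 1 - margin, w - 1 - margin])
        tubes.append(np.stack([a, b]))
    return tubes


def generate_vessel_image(
    tubes: list["np.ndarray | list[tuple[float, float]]"],
    width_px: float = 3.0,
    intensity: float = 100.0,
    background: "float | np.ndarray" = 10.0,
    noise_sigma: float = 0.0,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> VesselImageTruth:
    """Render tubes with Gaussian cross-sections onto a background field.

    ``tubes`` are polylines as (row, col) point lists in pixel coordinates;
    ``width_px`` is the full width at half maximum of the tube profile and
    also defines the ground-truth mask (distance to centreline <= width/2).
    Overlapping tubes combine by maximum.  Ground-truth per-tube lengths are
    the exact polyline lengths.
    """
    if width_px <= 0:
        raise ValueError("width_px must be positive")
    tubes_arr = [np.asarray(t, dtype=np.float64) for t in tubes]
    for t in tubes_arr:
        if t.ndim != 2 or t.shape[1] != 2:
            raise ValueError("each tube must be an (n, 2) point list")
        if (t[:, 0] < 0).any() or (t[:, 1] < 0).any() or (t[:, 0] > shape[0] - 1).any() or (t[:, 1] > shape[1] - 1).any():
            raise ValueError("tube extends outside the image bounds")
    sigma = width_px / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    signal = np.zeros(shape, dtype=np.float64)
    mask = np.zeros(shape, dtype=bool)
    lengths = []
    for t in tubes_arr:
        d = _min_distance_to_polyline(shape, t)
        signal = np.maximum(signal, intensity * np.exp(-(d**2) / (2.0 * sigma**2)))
        mask |= d <= width_px / 2.0
        lengths.append(polyline_length(t))
    rng = np.random.default_rng(seed)
    image = np.asarray(background, dtype=np.float64) + signal
    if noise_sigma > 0:
        image = image + rng.standard_normal(shape) * noise_sigma
    return VesselImageTruth(
        image=image, mask=mask, tube_lengths_px=lengths, width_px=width_px, tubes=tubes_arr
    )
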