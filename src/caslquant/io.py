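"""Reading and writing the standard formats the pipeline touches.

MRI volumes and maps are NIfTI-1 (via nibabel), microscopy stacks are TIFF
(via tifffile), tables are CSV (via pandas) and run configuration is
YAML or JSON.  Frame annotations (control/label interleave, experimental
condition) are attached at read time and carried explicitly — downstream
code never re-infers them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .geometry import VolumeGeometry

#: canonical column order of the tidy per-subject table
TABLE_COLUMNS = ["subject", "genotype", "age", "condition", "region", "bregma_level", "value"]


@dataclass
class ASLSeries:
    """A 4D image series with per-frame annotations.

    ``data`` has axis order (x, y, slice, frame).  ``frame_labels`` holds
    "control"/"label" per frame for ASL series (or None for e.g. an IR
    series); ``conditions`` holds "baseline"/"challenge" per frame.
    """

    data: np.ndarray
    geometry: VolumeGeometry
    frame_labels: list[str] | None = None
    conditions: list[str] | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D series, got {self.data.ndim}D")
        n = self.data.shape[3]
        if self.frame_labels is not None and len(self.frame_labels) != n:
            raise ValueError("frame_labels length must match frame count")
        if self.conditions is not None and len(self.conditions) != n:
            raise ValueError("conditions length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class QuantMap:
    """A 3D scalar map (T1, CBF or CVR) with geometry and validity mask."""

    data: np.ndarray
    geometry: VolumeGeometry
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D map, got {self.data.ndim}D")
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match map shape")


def default_frame_labels(n_frames: int, label_first: bool = False) -> list[str]:
    """Alternating control/label annotation (frame 0 is control by default)."""
    pair = ("label", "control") if label_first else ("control", "label")
    return [pair[i % 2] for i in range(n_frames)]


def cvr_session_conditions(n_frames: int, n_baseline: int = 120) -> list[str]:
    """Condition annotation for a baseline + hypercapnic-challenge session.

    The acquisition design is 7 min (120 frames) of baseline followed by
    7 min (120 frames) under the CO2 challenge.
    """
    return ["baseline" if i < n_baseline else "challenge" for i in range(n_frames)]


def _affine_from_geometry(geometry: VolumeGeometry) -> np.ndarray:
    aff = np.diag(list(geometry.voxel_size_mm) + [1.0])
    return aff


def read_volume_series(
    path: str | Path,
    label_first: bool = False,
    conditions: Sequence[str] | None = None,
    annotate: bool = True,
) -> ASLSeries:
    """Read a 4D NIfTI series and attach frame annotations.

    Parameters
    ----------
    path : path to a 4D NIfTI file.
    label_first : if True, frame 0 is a label frame (default: control first).
    conditions : optional per-frame condition annotation; by default all
        frames are "baseline".
    annotate : set False to skip control/label annotation (e.g. IR series).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt file
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected 4D series in {path}, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"geometry missing or invalid in {path}: zooms {zooms}")
    geometry = VolumeGeometry.from_zooms_mm(tuple(float(z) for z in zooms), data.shape[:3])
    labels = default_frame_labels(data.shape[3], label_first) if annotate else None
    conds = list(conditions) if conditions is not None else ["baseline"] * data.shape[3]
    return ASLSeries(data=data, geometry=geometry, frame_labels=labels, conditions=conds)


def write_volume_series(series: ASLSeries, path: str | Path) -> None:
    """Write a 4D series to NIfTI-1 with geometry in the header zooms."""
    img = nib.Nifti1Image(series.data, _affine_from_geometry(series.geometry))
    img.header.set_zooms(series.geometry.voxel_size_mm + (1.0,))
    nib.save(img, str(path))


def read_map(path: str | Path) -> QuantMap:
    """Read a 3D NIfTI map.  NaN voxels become invalid in the mask."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3D map in {path}, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"geometry missing or invalid in {path}: zooms {zooms}")
    geometry = VolumeGeometry.from_zooms_mm(tuple(float(z) for z in zooms), data.shape)
    mask = np.isfinite(data)
    return QuantMap(data=np.nan_to_num(data), geometry=geometry, mask=mask)


def write_map(qmap: QuantMap, path: str | Path) -> None:
    """Write a 3D map to NIfTI-1; invalid voxels are written as NaN."""
    out = qmap.data.astype(np.float64).copy()
    out[~qmap.mask] = np.nan
    img = nib.Nifti1Image(out, _affine_from_geometry(qmap.geometry))
    img.header.set_zooms(qmap.geometry.voxel_size_mm)
    nib.save(img, str(path))


def write_table(records: Sequence[dict], path: str | Path) -> None:
    """Write per-subject/per-ROI records to CSV with the canonical header.

    Rows are sorted on all columns so re-writing the same records yields a
    byte-identical file.
    """
    df = pd.DataFrame(list(records), columns=TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(TABLE_COLUMNS, kind="mergesort").reset_index(drop=True)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise IOError(f"could not write table to {path}: {exc}") from exc


@dataclass
class RunConfig:
    """Configuration for a pipeline run; the seed is recorded in all outputs."""

    inputs: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)
    smoothing_fwhm_factor: float = 2.0
    fdr_q: float = 0.05
    cluster_k: int = 10
    vessel: dict = field(default_factory=lambda: {"background_radius_px": 50, "tubeness_scales_px": [1, 2, 4], "threshold": None})
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must be in (0, 1)")
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**payload)

    def to_file(self, path: str | Path) -> None:
        payload = {
            "inputs": self.inputs,
            "acquisition": self.acquisition,
            "smoothing_fwhm_factor": self.smoothing_fwhm_factor,
            "fdr_q": self.fdr_q,
            "cluster_k": self.cluster_k,
            "vessel": self.vessel,
            "seed": self.seed,
        }
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload))
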