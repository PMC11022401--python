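"""Voxel-based and region-based group comparisons with FDR control.

Two analysis routes mirror common practice in small-animal perfusion MRI:

* voxel-based analysis (VBA): a voxelwise two-sample t-test between groups,
  Benjamini-Hochberg FDR across in-mask voxels, and a cluster-extent filter
  (surviving voxels grouped into connected components; components smaller
  than k voxels discarded);
* region-based analysis (RBA): mean parameter values per atlas region, then
  multiple two-sample t-tests with FDR correction.

The module also implements the robust outlier screening used for
image-based measurements: values outside median +/- factor * MAD are
rejected, where MAD is the raw (unscaled) median absolute deviation, and an
animal contributing fewer than a minimum number of retained images for a
region is dropped from that region entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class ROIAtlas:
    """Region-label map plus id -> (name, bregma level in mm) lookup."""

    labels: np.ndarray
    regions: dict[int, tuple[str, float]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        ids = list(self.regions)
        if len(ids) != len(set(ids)):
            raise ValueError("region ids must be unique")
        for rid in ids:
            if not (self.labels == rid).any():
                raise ValueError(f"region {rid} ({self.regions[rid][0]}) is empty")


def extract_roi_means(qmap, atlas: ROIAtlas) -> pd.DataFrame:
    """Mean map value over valid voxels per atlas region.

    Returns a tidy frame (region, bregma_level, mean, n_voxels, missing);
    a region whose voxels are all invalid is flagged missing, never
    reported as zero.
    """
    if qmap.data.shape != atlas.labels.shape:
        raise ValueError("atlas is not aligned to the map geometry")
    rows = []
    for rid, (name, bregma) in atlas.regions.items():
        sel = (atlas.labels == rid) & qmap.mask
        n = int(sel.sum())
        rows.append(
            {
                "region": name,
                "region_id": rid,
                "bregma_level": bregma,
                "mean": float(qmap.data[sel].mean()) if n else np.nan,
                "n_voxels": n,
                "missing": n == 0,
            }
        )
    return pd.DataFrame(rows)


def two_sample_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    variance_mode: str = "pooled",
) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled-variance Student by default).

    ``variance_mode="welch"`` switches to the unequal-variance form.  The
    degenerate case of zero variance in both groups with equal means
    returns (0, 1) by convention.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variance_mode not in ("pooled", "welch"):
        raise ValueError("variance_mode must be 'pooled' or 'welch'")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=(variance_mode == "pooled"))
    return float(t), float(p)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns (adjusted q-values, rejection flags at level ``q``).  Adjusted
    values are monotone non-decreasing in the sorted p-value order.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_adj, reject


_STRUCTURES = {
    "6": ndimage.generate_binary_structure(3, 1),
    "18": ndimage.generate_binary_structure(3, 2),
    "26": ndimage.generate_binary_structure(3, 3),
}


def _inplane_8_structure() -> np.ndarray:
    s = np.zeros((3, 3, 3), dtype=bool)
    s[:, :, 1] = True
    return s


def voxelwise_group_map(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    mask: np.ndarray,
    q: float = 0.05,
    cluster_k: int = 10,
    connectivity: str = "6",
    variance_mode: str = "pooled",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Voxel-based group comparison with FDR and cluster-extent filtering.

    ``maps_a``/``maps_b`` stack subjects on the last axis (x, y, z, n).
    Voxelwise two-sample t-values are thresholded by BH-FDR at level ``q``
    across in-mask voxels; surviving voxels are grouped into connected
    components (default 6-neighbour face connectivity, ``"inplane8"`` for
    slicewise 8-connectivity) and components smaller than ``cluster_k``
    voxels are removed.

    Returns the thresholded t-map (zero where not surviving) and a cluster
    table (cluster id, size, peak |t|, centroid voxel indices).
    """
    if maps_a.shape[:3] != maps_b.shape[:3] or maps_a.shape[:3] != mask.shape:
        raise ValueError("group maps and mask geometries do not match")
    if maps_a.shape[3] < 2 or maps_b.shape[3] < 2:
        raise ValueError("each group needs at least 2 subjects")
    mask = np.asarray(mask, dtype=bool)
    A = maps_a[mask]  # (nvox, na)
    B = maps_b[mask]
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if variance_mode == "pooled":
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            dof = np.full(ma.shape, na + nb - 2, dtype=np.float64)
        else:
            se = np.sqrt(va / na + vb / nb)
            dof = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        t = np.where(se > 0, (ma - mb) / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    p[se == 0] = 1.0
    _, reject = bh_fdr(p, q=q)

    surviving = np.zeros(mask.shape, dtype=bool)
    surviving[mask] = reject
    structure = _inplane_8_structure() if connectivity == "inplane8" else _STRUCTURES[connectivity]
    labeled, n_clusters = ndimage.label(surviving, structure=structure)
    t_map = np.zeros(mask.shape, dtype=np.float64)
    t_map[mask] = t
    rows = []
    out_t = np.zeros_like(t_map)
    kept = 0
    for cid in range(1, n_clusters + 1):
        sel = labeled == cid
        size = int(sel.sum())
        if size < cluster_k:
            continue
        kept += 1
        out_t[sel] = t_map[sel]
        peak = float(np.abs(t_map[sel]).max())
        centroid = tuple(float(c) for c in np.argwhere(sel).mean(axis=0))
        rows.append({"cluster": kept, "size": size, "peak_abs_t": peak, "centroid": centroid})
    table = pd.DataFrame(rows, columns=["cluster", "size", "peak_abs_t", "centroid"])
    return out_t, table


def mad_outlier_filter(
    values: np.ndarray,
    factor: float = 3.0,
    scaled: bool = False,
) -> np.ndarray:
    """Keep values inside median +/- factor * MAD (inclusive).

    MAD is the raw median of absolute deviations from the median by
    default (no 1.4826 consistency factor); ``scaled=True`` applies it.
    Note the degenerate case: when more than half the values coincide the
    MAD is zero and only values exactly equal to the median are kept.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        return np.array([], dtype=bool)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if scaled:
        mad *= 1.4826
    lo, hi = med - factor * mad, med + factor * mad
    return (x >= lo) & (x <= hi)


def aggregate_if_measurements(
    per_image_records: pd.DataFrame,
    min_images: int = 3,
    factor: float = 3.0,
    id_cell_columns: tuple[str, ...] = ("region",),
    value_column: str = "value",
) -> pd.DataFrame:
    """Two-stage robust aggregation of per-image measurements per animal.

    Stage 1: within each (animal, region) cell, reject images outside
    median +/- factor * MAD; if fewer than ``min_images`` images remain the
    animal is discarded for that region.  Stage 2: average retained images
    per (animal, region), then apply the same MAD screen at the animal level
    within each cell defined by ``id_cell_columns`` (by default per region;
    add e.g. "genotype", "age" to screen within finer cells).

    Input needs columns animal, region, ``value_column`` (an image column is
    optional).  Returns per-animal records with n_images retained.
    """
    df = per_image_records.copy()
    required = {"animal", "region", value_column}
    if not required.issubset(df.columns):
        raise ValueError(f"records must carry columns {sorted(required)}")
    kept_rows = []
    for (animal, region), grp in df.groupby(["animal", "region"], sort=True):
        keep = mad_outlier_filter(grp[value_column].to_numpy(), factor=factor)
        retained = grp[keep]
        if len(retained) < min_images:
            continue  # animal discarded for this region
        row = {"animal": animal, "region": region,
               value_column: float(retained[value_column].mean()),
               "n_images": int(len(retained))}
        for col in df.columns:
            if col not in row and col not in ("image",):
                vals = retained[col].unique()
                if len(vals) == 1:
                    row[col] = vals[0]
        kept_rows.append(row)
    per_animal = pd.DataFrame(kept_rows)
    if per_animal.empty:
        return per_animal
    cell_cols = [c for c in id_cell_columns if c in per_animal.columns]
    keep_mask = np.zeros(len(per_animal), dtype=bool)
    for _, grp in per_animal.groupby(cell_cols or ["region"], sort=True):
        keep = mad_outlier_filter(grp[value_column].to_numpy(), factor=factor)
        keep_mask[grp.index.to_numpy()] = keep
    return per_animal[keep_mask].reset_index(drop=True)


def region_stat_table(
    records: pd.DataFrame,
    group_column: str = "genotype",
    groups: tuple[str, str] | None = None,
    value_column: str = "value",
    q: float = 0.05,
    variance_mode: str = "pooled",
) -> pd.DataFrame:
    """Region-based analysis: two-sample tests per region with BH-FDR.

    Records need columns region, bregma_level (optional), ``group_column``
    and ``value_column``.  Returns rows of (region, bregma_level, t, p,
    q_adjusted, significant, group means and ns) with q >= p row-wise.
    """
    df = records
    levels = groups or tuple(pd.unique(df[group_column]))[:2]
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    keys = ["region"] + (["bregma_level"] if "bregma_level" in df.columns else [])
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        a = grp.loc[grp[group_column] == levels[0], value_column].to_numpy()
        b = grp.loc[grp[group_column] == levels[1], value_column].to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        t, p = two_sample_test(a, b, variance_mode=variance_mode)
        rows.append(dict(zip(keys, key)) | {
            "t": t, "p": p,
            f"mean_{levels[0]}": float(a.mean()), f"mean_{levels[1]}": float(b.mean()),
            f"n_{levels[0]}": int(a.size), f"n_{levels[1]}": int(b.size),
        })
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    q_adj, reject = bh_fdr(table["p"].to_numpy(), q=q)
    table["q_adjusted"] = q_adj
    table["significant"] = reject
    return table
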