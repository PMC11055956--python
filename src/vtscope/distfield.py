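"""Distance-field analysis of vessel supply.

Anisotropic Euclidean distance from every voxel inside the VTS (and
outside the vessels) to the nearest CD31-positive voxel, distance
histograms, the supply index, cell-to-structure distances and the
Col IV / vessel association partition.

Distances are voxel-centre to voxel-centre in µm.  Voxels outside the
domain carry NaN as an explicit sentinel; only the optional 8-bit export
uses 255-as-outside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .segment import CellSet


@dataclass
class DistanceField:
    """Per-voxel distance (µm) to the nearest vessel voxel.

    ``values`` is NaN outside the domain (outside the VTS, inside the PV,
    or everywhere when there is no vessel at all).
    """

    values: np.ndarray
    spacing: tuple
    has_vessels: bool = True

    @property
    def domain(self) -> np.ndarray:
        return np.isfinite(self.values)

    def finite_values(self) -> np.ndarray:
        return self.values[self.domain]

    def median(self) -> float:
        v = self.finite_values()
        return float(np.median(v)) if v.size else np.nan

    def to_uint8(self, max_distance: float = 127.0) -> np.ndarray:
        """Legacy-style 8-bit export: 0..254 encode distance, 255 = outside."""
        scaled = np.clip(self.values / max_distance, 0.0, 1.0) * 254.0
        out = np.where(self.domain, np.round(scaled), 255.0)
        return out.astype(np.uint8)


def pv_distance_field(
    cd31_mask: np.ndarray, vts_mask: np.ndarray, spacing
) -> DistanceField:
    """Distance of each in-VTS, non-PV voxel to the nearest PV voxel."""
    cd31 = np.asarray(cd31_mask, bool)
    vts = np.asarray(vts_mask, bool)
    if cd31.shape != vts.shape:
        raise ValueError("masks must be congruent")
    spacing = tuple(float(s) for s in spacing)
    values = np.full(cd31.shape, np.nan, dtype=np.float64)
    if not cd31.any():
        warnings.warn("empty CD31 mask: distance field is all-sentinel")
        return DistanceField(values, spacing, has_vessels=False)
    dist = ndimage.distance_transform_edt(~cd31, sampling=spacing)
    domain = vts & ~cd31
    values[domain] = dist[domain]
    return DistanceField(values, spacing)


def distance_histogram(
    field: DistanceField, bin_width: float = 2.0
) -> pd.DataFrame:
    """Histogram of the in-domain distances with summary stats in attrs."""
    v = field.finite_values()
    if v.size == 0:
        df = pd.DataFrame(columns=["bin_left_um", "bin_right_um", "count"])
        df.attrs.update(median_um=np.nan, mean_um=np.nan, n=0)
        return df
    n_bins = max(1, int(np.ceil((v.max() + 1e-9) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(v, bins=edges)
    df = pd.DataFrame(
        {"bin_left_um": edges[:-1], "bin_right_um": edges[1:], "count": counts}
    )
    df.attrs.update(median_um=float(np.median(v)), mean_um=float(v.mean()), n=int(v.size))
    return df


def supply_index(cd31_relative_volume_pct: float, median_distance_um: float) -> float:
    """Supply index: relative CD31 volume (%) over median PV distance (µm).

    Higher values indicate a denser and more homogeneously distributed
    pseudovasculature.
    """
    if not np.isfinite(median_distance_um) or median_distance_um <= 0:
        raise ValueError("median distance must be positive and defined")
    if not 0 < cd31_relative_volume_pct <= 100:
        raise ValueError("relative volume must be in (0, 100] percent")
    return float(cd31_relative_volume_pct / median_distance_um)


def cell_distances(
    cells: CellSet,
    target_mask: np.ndarray,
    spacing,
    mode: str = "mask",
) -> pd.DataFrame:
    """Per-cell distance (µm) to a target structure.

    mode="mask": distance to the nearest target voxel (0 inside the target).
    mode="surface": distance to the target's boundary, measured from either
    side (a cell at the centre of a spherical mask of radius R reports ~R).
    """
    if mode not in ("mask", "surface"):
        raise ValueError("mode must be 'mask' or 'surface'")
    spacing = np.asarray(spacing, dtype=float)
    target = np.asarray(target_mask, bool)
    n = cells.count
    if n == 0:
        df = pd.DataFrame(columns=["z_um", "y_um", "x_um", "distance_um"])
        df.attrs.update(median_um=np.nan, role=cells.role)
        return df
    if not target.any():
        dist_at = np.full(n, np.nan)
    else:
        if mode == "mask":
            dist = ndimage.distance_transform_edt(~target, sampling=spacing)
        else:
            inside = ndimage.distance_transform_edt(target, sampling=spacing)
            outside = ndimage.distance_transform_edt(~target, sampling=spacing)
            dist = inside + outside  # one term is 0 everywhere
        idx = np.round(cells.centroids / spacing).astype(int)
        idx = np.clip(idx, 0, np.array(target.shape) - 1)
        dist_at = dist[tuple(idx.T)]
    df = pd.DataFrame(
        {
            "z_um": cells.centroids[:, 0],
            "y_um": cells.centroids[:, 1],
            "x_um": cells.centroids[:, 2],
            "distance_um": dist_at,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        df.attrs.update(median_um=float(np.nanmedian(dist_at)), role=cells.role)
    return df


def complementary_cell_distances(cells: CellSet, other: CellSet) -> pd.DataFrame:
    """Per-cell distance to the nearest cell of a complementary population."""
    n = cells.count
    if n == 0 or other.count == 0:
        df = pd.DataFrame(columns=["z_um", "y_um", "x_um", "distance_um"])
        df.attrs.update(median_um=np.nan, role=cells.role)
        return df
    tree = cKDTree(other.centroids)
    d, _ = tree.query(cells.centroids)
    df = pd.DataFrame(
        {
            "z_um": cells.centroids[:, 0],
            "y_um": cells.centroids[:, 1],
            "x_um": cells.centroids[:, 2],
            "distance_um": d,
        }
    )
    df.attrs.update(median_um=float(np.median(d)), role=cells.role)
    return df


def colIV_association(
    colIV_mask: np.ndarray,
    cd31_mask: np.ndarray,
    vts_mask: np.ndarray,
    d_assoc: float = 3.0,
    spacing=(1.0, 1.0, 1.0),
) -> dict:
    """Partition Col IV voxels by their relation to the pseudovessels.

    Classes: PV-associated (within ``d_assoc`` µm of CD31), in-VTS but not
    associated, and outside the VTS.  Returns the class fractions of the
    Col IV volume plus the associated-volume / CD31-volume ratio.
    """
    colIV = np.asarray(colIV_mask, bool)
    cd31 = np.asarray(cd31_mask, bool)
    vts = np.asarray(vts_mask, bool)
    if not (colIV.shape == cd31.shape == vts.shape):
        raise ValueError("masks must be congruent")
    spacing = np.asarray(spacing, dtype=float)
    n_col = int(colIV.sum())
    result = {
        "n_colIV_voxels": n_col,
        "associated_fraction": 0.0,
        "in_vts_nonassociated_fraction": 0.0,
        "outside_vts_fraction": 0.0,
        "associated_over_cd31": 0.0,
    }
    if n_col == 0:
        return result
    if not cd31.any():
        warnings.warn("empty CD31 mask: Col IV association fraction is 0")
        near = np.zeros_like(colIV)
    else:
        dist = ndimage.distance_transform_edt(~cd31, sampling=spacing)
        near = dist <= d_assoc
    assoc = colIV & near
    in_vts_free = colIV & vts & ~near
    outside = colIV & ~vts & ~near
    n_cd31 = int(cd31.sum())
    result.update(
        associated_fraction=float(assoc.sum()) / n_col,
        in_vts_nonassociated_fraction=float(in_vts_free.sum()) / n_col,
        outside_vts_fraction=float(outside.sum()) / n_col,
        associated_over_cd31=(float(assoc.sum()) / n_cd31 if n_cd31 else 0.0),
    )
    return result
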