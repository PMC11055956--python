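"""Per-channel compartment segmentation and point-like cell detection.

Channels are segmented independently (2 µm surface detail smoothing,
threshold, restriction to the VTS body, size filter, 26-connected
labelling).  Point-like cells (macrophages, Hif1a+ nuclei, and the orb
representation of tumor cells and fibroblasts) are localized by a
single-scale Laplacian-of-Gaussian detector matched to the nominal
10 µm cell diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

from .config import PipelineConfig, ConfigurationError
from .imgio import MultichannelStack
from .preprocess import smooth_um, _apply_threshold

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CompartmentSegmentation:
    """Foreground mask plus connected-object statistics for one channel."""

    role: str
    mask: np.ndarray                      # bool (Z, Y, X)
    labels: np.ndarray                    # int32 (Z, Y, X), 0 = background
    objects: pd.DataFrame                 # id, volume_um3, centroid z/y/x µm
    threshold: float
    spacing: tuple
    settings: dict = field(default_factory=dict)

    @property
    def volume(self) -> float:
        """Total foreground volume in µm³."""
        return float(self.mask.sum()) * float(np.prod(self.spacing))

    @property
    def n_objects(self) -> int:
        return len(self.objects)


@dataclass
class CellSet:
    """Detected point-like cells of one population."""

    role: str
    centroids: np.ndarray                 # (N, 3) µm, (z, y, x)
    diameter: float = 10.0
    quality: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")

    @property
    def count(self) -> int:
        return len(self.centroids)

    def density(self, reference_volume_um3: float) -> float:
        """Cells per mm³ of reference volume."""
        return self.count / reference_volume_um3 * 1e9 if reference_volume_um3 > 0 else np.nan


def _object_table(labels: np.ndarray, n: int, spacing) -> pd.DataFrame:
    voxel_vol = float(np.prod(spacing))
    if n == 0:
        return pd.DataFrame(columns=["id", "volume_um3", "z_um", "y_um", "x_um"])
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones(labels.shape, dtype=np.int8), labels, idx)
    centroids = np.array(ndimage.center_of_mass(np.ones(labels.shape), labels, idx))
    centroids = centroids * np.asarray(spacing)
    return pd.DataFrame(
        {
            "id": idx,
            "volume_um3": counts * voxel_vol,
            "z_um": centroids[:, 0],
            "y_um": centroids[:, 1],
            "x_um": centroids[:, 2],
        }
    )


def segment_channel(
    stack: MultichannelStack,
    role: str,
    config: PipelineConfig | None = None,
    vts_mask: np.ndarray | None = None,
) -> CompartmentSegmentation:
    """Segment one channel into foreground and connected objects.

    Smooth at the channel surface detail (default 2 µm), threshold
    (default Otsu), intersect with the VTS mask, drop objects below
    ``min_object_volume`` and label 26-connected components.
    """
    config = config or PipelineConfig()
    if not stack.has_role(role):
        raise ConfigurationError(f"stack has no channel with role {role!r}")
    volume = stack.channel(role)
    smoothed = smooth_um(volume, config.surface_detail_channel, stack.spacing)
    thr = _apply_threshold(smoothed, config.threshold_for(role))
    mask = smoothed > thr
    if vts_mask is not None:
        mask &= vts_mask
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    if n:
        voxel_vol = float(np.prod(stack.spacing))
        min_vox = config.min_object_volume / voxel_vol
        counts = ndimage.sum_labels(np.ones(labels.shape, np.int8), labels,
                                    np.arange(1, n + 1))
        keep = np.flatnonzero(counts >= min_vox) + 1
        if len(keep) < n:
            mask = np.isin(labels, keep)
            labels, n = ndimage.label(mask, structure=_STRUCT26)
    table = _object_table(labels, n, stack.spacing)
    return CompartmentSegmentation(
        role=role,
        mask=mask,
        labels=labels.astype(np.int32),
        objects=table,
        threshold=thr,
        spacing=stack.spacing,
        settings={
            "surface_detail": config.surface_detail_channel,
            "threshold_rule": vars(config.threshold_for(role)),
            "min_object_volume": config.min_object_volume,
        },
    )


def detect_cells(
    stack: MultichannelStack,
    role: str,
    config: PipelineConfig | None = None,
    vts_mask: np.ndarray | None = None,
) -> CellSet:
    """Localize point-like cells as ~``cell_diameter`` µm blobs.

    Single-scale LoG: the channel is filtered with a Laplacian of Gaussian
    at sigma = diameter / (2*sqrt(3)) µm (the scale at which the response
    of a ball of that diameter peaks), the response negated so bright blobs
    are maxima, and local maxima above mean + k*std of the response kept.
    Centroids are reported in µm; detection is deterministic.
    """
    config = config or PipelineConfig()
    if not stack.has_role(role):
        raise ConfigurationError(f"stack has no channel with role {role!r}")
    d = config.cell_diameter
    spacing = np.asarray(stack.spacing)
    sigma_um = d / (2.0 * np.sqrt(3.0))
    volume = np.asarray(stack.channel(role), dtype=np.float32)
    response = -ndimage.gaussian_laplace(volume, sigma=sigma_um / spacing)
    thr = float(response.mean() + config.cell_quality_k * response.std())
    min_dist_vox = np.maximum((0.6 * d) / spacing, 1).astype(int)
    # anisotropic exclusion neighbourhood for the maxima search
    footprint = np.ones(2 * min_dist_vox + 1, dtype=bool)
    peaks = peak_local_max(
        response, footprint=footprint, threshold_abs=thr, exclude_border=False
    )
    if len(peaks) and vts_mask is not None:
        # a cell centre sits roughly half a diameter inside the tissue;
        # the depth cut also rejects the edge response of the VTS surface
        depth = ndimage.distance_transform_edt(vts_mask, sampling=spacing)
        peaks = peaks[depth[tuple(peaks.T)] >= 0.45 * d]
    if len(peaks) == 0:
        return CellSet(role=role, centroids=np.empty((0, 3)), diameter=d)
    # deterministic ordering
    order = np.lexsort((peaks[:, 2], peaks[:, 1], peaks[:, 0]))
    peaks = peaks[order]
    quality = response[tuple(peaks.T)]
    centroids = peaks * spacing
    return CellSet(role=role, centroids=centroids, diameter=d, quality=quality)


def object_volume_distribution(seg: CompartmentSegmentation) -> pd.DataFrame:
    """Per-object volumes, sorted descending, with n/median/max in attrs."""
    table = seg.objects[["id", "volume_um3"]].sort_values(
        "volume_um3", ascending=False, ignore_index=True
    )
    table.attrs["n"] = len(table)
    table.attrs["median"] = float(table["volume_um3"].median()) if len(table) else np.nan
    table.attrs["max"] = float(table["volume_um3"].max()) if len(table) else np.nan
    return table


def relative_volume(seg: CompartmentSegmentation, vts_mask: np.ndarray) -> float:
    """Fraction of the VTS volume occupied by this compartment, in [0, 1]."""
    n_vts = int(vts_mask.sum())
    if n_vts == 0:
        return np.nan
    return float((seg.mask & vts_mask).sum()) / n_vts
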