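"""Pipeline configuration.

All length-like settings are in micrometres; the voxel grid is indexed
(z, y, x) with the physical position of a voxel centre equal to
``index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

#: Channel roles understood by the pipeline.
KNOWN_ROLES = (
    "vts_combined",
    "tumor",
    "fibroblast",
    "cd31",
    "cd11b",
    "colIV",
    "hif1a",
    "custom",
)

#: Roles that are detected as point-like 10 µm cells rather than volumes only.
CELL_ROLES = ("tumor", "fibroblast", "cd11b", "hif1a")


@dataclass
class ThresholdRule:
    """Signal/background threshold for one channel.

    method
        ``"otsu"`` (default, parameter free), ``"quantile"`` (value in (0, 1),
        threshold at that intensity quantile) or ``"absolute"`` (value in
        intensity units).
    """

    method: str = "otsu"
    value: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "quantile", "absolute"):
            raise ConfigurationError(f"unknown threshold method {self.method!r}")
        if self.method == "quantile":
            if self.value is None or not (0.0 < self.value < 1.0):
                raise ConfigurationError("quantile threshold needs value in (0, 1)")
        if self.method == "absolute" and self.value is None:
            raise ConfigurationError("absolute threshold needs a value")


class ConfigurationError(ValueError):
    """Raised for invalid pipeline or phantom configuration."""


@dataclass
class PipelineConfig:
    """Settings for the full VTS analysis pipeline.

    Attributes
    ----------
    median_radius
        Half-width, in voxels per axis, of the box neighbourhood of the 3D
        median noise filter (2.0 -> a 5x5x5 box, the convention of the
        eponymous ImageJ filter).
    surface_detail_channel, surface_detail_vts
        Surface detail in µm used when segmenting individual channels (2 µm)
        and the combined-channel VTS body (10 µm).  Interpreted as Gaussian
        pre-smoothing with sigma = detail / 2 before thresholding.
    thresholds
        Per-role :class:`ThresholdRule`; roles not listed use the default rule.
    min_object_volume
        Connected objects smaller than this (µm³) are discarded.
    cell_diameter
        Nominal diameter of point-like cells (µm); they are rendered and
        detected as 10 µm orbs.
    cell_quality_k
        Blob-detection quality cut: local maxima of the negated
        Laplacian-of-Gaussian response are kept if above
        mean + k * std of the response volume.
    colIV_association_distance
        Distance (µm) within which Col IV is counted as apposed to a vessel.
    spur_prune_length
        Skeleton spur segments shorter than this (µm) are pruned.
    distance_bin_width
        Bin width (µm) of vessel-distance histograms.
    distance_export_max
        Distance mapped to grey level 254 in the optional 8-bit export;
        255 marks out-of-VTS voxels.
    spacing
        Fallback voxel spacing (dz, dy, dx) in µm when a file carries no
        physical metadata; 0.5 µm pixels with a 1 µm z-step by default.
    """

    median_radius: float = 2.0
    surface_detail_channel: float = 2.0
    surface_detail_vts: float = 10.0
    thresholds: dict = field(default_factory=dict)
    min_object_volume: float = 100.0
    cell_diameter: float = 10.0
    cell_quality_k: float = 5.0
    colIV_association_distance: float = 3.0
    spur_prune_length: float = 5.0
    distance_bin_width: float = 2.0
    distance_export_max: float = 127.0
    spacing: tuple = (1.0, 0.5, 0.5)
    channel_roles: dict = field(default_factory=dict)
    seed: int = 0
    strict: bool = False

    def __post_init__(self) -> None:
        for name in (
            "surface_detail_channel",
            "surface_detail_vts",
            "cell_diameter",
            "colIV_association_distance",
            "distance_bin_width",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.median_radius < 0 or self.spur_prune_length < 0:
            raise ConfigurationError("radii/prune lengths must be >= 0")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be three positive lengths (dz, dy, dx)")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.thresholds = {
            role: rule if isinstance(rule, ThresholdRule) else ThresholdRule(**rule)
            for role, rule in self.thresholds.items()
        }
        self.channel_roles = {int(k): str(v) for k, v in self.channel_roles.items()}

    def threshold_for(self, role: str) -> ThresholdRule:
        return self.thresholds.get(role, ThresholdRule())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spacing"] = list(self.spacing)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
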