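"""Multichannel stack container and OME-TIFF round-trip I/O.

Stacks are stored (channel, z, y, x) with physical voxel spacing
(dz, dy, dx) in µm and a role name per channel.  Spacing and roles are
embedded in OME-XML metadata on write and recovered on read; metadata in
the file takes precedence over the configuration.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .config import PipelineConfig, ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class MultichannelStack:
    """A 4-D fluorescence volume with physical metadata.

    voxels : (C, Z, Y, X) array, unsigned integer or float32
    spacing : (dz, dy, dx) in µm
    channel_roles : channel index -> role name
    """

    voxels: np.ndarray
    spacing: tuple
    channel_roles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 4 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty (C, Z, Y, X) grid")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (dz, dy, dx)")
        self.spacing = tuple(float(s) for s in self.spacing)
        bad = [c for c in self.channel_roles if not 0 <= int(c) < self.n_channels]
        if bad:
            raise ValueError(f"channel_roles refer to missing channels: {bad}")
        self.channel_roles = {int(k): str(v) for k, v in self.channel_roles.items()}

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple:
        """Spatial shape (Z, Y, X)."""
        return self.voxels.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    def channel(self, role: str) -> np.ndarray:
        """Return the (Z, Y, X) volume for a role."""
        idx = self.index_of(role)
        return self.voxels[idx]

    def index_of(self, role: str) -> int:
        for idx, r in self.channel_roles.items():
            if r == role:
                return idx
        raise ConfigurationError(f"no channel with role {role!r}")

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles.values()

    def with_channel(self, volume: np.ndarray, role: str) -> "MultichannelStack":
        """Return a new stack with one channel appended."""
        if volume.shape != self.shape:
            raise ValueError("appended channel shape mismatch")
        voxels = np.concatenate([self.voxels, volume[None].astype(self.voxels.dtype)])
        roles = dict(self.channel_roles)
        roles[self.n_channels] = role
        return MultichannelStack(voxels, self.spacing, roles)


def write_stack(stack: MultichannelStack, path: str | Path) -> None:
    """Write a lossless OME-TIFF with spacing and channel-role metadata."""
    voxels = stack.voxels
    if voxels.dtype not in (np.uint8, np.uint16, np.float32):
        voxels = voxels.astype(np.float32)
    names = [stack.channel_roles.get(c, f"channel{c}") for c in range(stack.n_channels)]
    dz, dy, dx = stack.spacing
    try:
        tifffile.imwrite(
            path,
            voxels,
            ome=True,
            photometric="minisblack",
            metadata={
                "axes": "CZYX",
                "PhysicalSizeX": dx,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": dy,
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZ": dz,
                "PhysicalSizeZUnit": "µm",
                "Channel": {"Name": names},
            },
        )
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def _parse_ome(xml: str):
    """Extract (spacing, channel names) from OME-XML; None where absent."""
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return None, None
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pix = root.find(".//ome:Pixels", ns) if ns else root.find(".//Pixels")
    if pix is None:
        return None, None
    spacing = None
    if all(pix.get(f"PhysicalSize{a}") for a in "XYZ"):
        spacing = (
            float(pix.get("PhysicalSizeZ")),
            float(pix.get("PhysicalSizeY")),
            float(pix.get("PhysicalSizeX")),
        )
    chans = pix.findall("ome:Channel", ns) if ns else pix.findall("Channel")
    names = [c.get("Name") for c in chans] if chans else None
    if names and any(n is None for n in names):
        names = None
    return spacing, names


def read_stack(path: str | Path, config: PipelineConfig | None = None) -> MultichannelStack:
    """Read a TIFF/OME-TIFF stack.

    Spacing and channel roles come from the file's OME metadata when present,
    falling back to ``config``; file metadata wins on conflict (logged).
    """
    config = config or PipelineConfig()
    try:
        with tifffile.TiffFile(path) as tif:
            voxels = tif.series[0].asarray()
            meta_spacing, meta_names = (
                _parse_ome(tif.ome_metadata) if tif.ome_metadata else (None, None)
            )
    except (OSError, ValueError, IndexError) as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    if voxels.ndim == 3:
        voxels = voxels[None]
    if voxels.ndim != 4:
        raise IOError(f"{path}: expected a (C,)Z,Y,X stack, got shape {voxels.shape}")

    spacing = tuple(config.spacing)
    if meta_spacing is not None:
        if tuple(meta_spacing) != spacing and config.spacing is not None:
            log.info(
                "%s: file spacing %s overrides config spacing %s",
                path, meta_spacing, spacing,
            )
        spacing = tuple(meta_spacing)

    n_chan = voxels.shape[0]
    if meta_names is not None:
        if len(meta_names) != n_chan:
            raise ConfigurationError(
                f"{path}: {n_chan} channels but {len(meta_names)} channel names"
            )
        roles = {i: name for i, name in enumerate(meta_names)}
    elif config.channel_roles:
        if len(config.channel_roles) != n_chan:
            raise ConfigurationError(
                f"{path}: {n_chan} channels but config names {len(config.channel_roles)}"
            )
        roles = dict(config.channel_roles)
    else:
        roles = {i: f"channel{i}" for i in range(n_chan)}
    return MultichannelStack(voxels, spacing, roles)
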