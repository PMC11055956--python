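"""Synthetic vascularized-spheroid phantoms with full ground truth.

The generator emulates the light-sheet stacks the analysis pipeline
consumes: a spheroid body, an embedded branching pseudovessel network
rendered into a CD31 channel, point-like cells rendered as ~10 µm orbs in
their own channels, PSF blur, and Poisson + Gaussian noise.  Ground truth
(centerlines with per-point radii, noiseless masks, cell centroids) is
returned alongside so every downstream stage can be validated without
microscope data.

It also generates synthetic treated/control ratio tables with emulated
observer scores for exercising the VEI calibration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import ConfigurationError
from .imgio import MultichannelStack

log = logging.getLogger(__name__)


@dataclass
class VesselParams:
    """Stochastic branching-tree growth settings.

    n_roots : number of independent networks seeded inside the spheroid
    branch_prob : probability of spawning a side branch per growth step
    radius_range : (min, max) vessel radius in µm; radii taper root -> tip
    step_length : centreline step in µm
    max_depth : maximum branching depth
    """

    n_roots: int = 3
    branch_prob: float = 0.12
    radius_range: tuple = (1.5, 4.0)
    step_length: float = 4.0
    max_depth: int = 4

    def __post_init__(self) -> None:
        if self.n_roots < 0 or self.max_depth < 0:
            raise ConfigurationError("counts must be >= 0")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ConfigurationError("branch_prob must be a probability")
        rmin, rmax = self.radius_range
        if not 0 < rmin <= rmax:
            raise ConfigurationError("radius_range must satisfy 0 < min <= max")
        if self.step_length <= 0:
            raise ConfigurationError("step_length must be positive")


@dataclass
class CellParams:
    """One point-like cell population rendered as orbs."""

    count: int = 25
    orb_diameter: float = 10.0
    placement: str = "uniform"  # uniform | shell | clustered
    min_separation: float = 15.0
    intensity: float = 220.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ConfigurationError("cell count must be >= 0")
        if self.orb_diameter <= 0:
            raise ConfigurationError("orb_diameter must be positive")
        if self.placement not in ("uniform", "shell", "clustered"):
            raise ConfigurationError(f"unknown placement {self.placement!r}")


@dataclass
class NoiseParams:
    """Generic fluorescence noise model: shot noise + read noise + offset."""

    photon_scale: float = 2.0
    gaussian_sd: float = 2.0
    background_level: float = 8.0

    def __post_init__(self) -> None:
        if self.photon_scale < 0 or self.gaussian_sd < 0 or self.background_level < 0:
            raise ConfigurationError("noise parameters must be >= 0")


#: body-texture intensity of the volume-filling compartments
DEFAULT_BODY_INTENSITY = {"tumor": 70.0, "fibroblast": 110.0}


@dataclass
class PhantomSpec:
    """Full description of one synthetic VTS stack.

    spheroid_radius is in µm; real VTSs are ~300–500 µm in diameter but the
    default here is sized so the stack stays tractable at the native
    0.5 x 0.5 x 1 µm voxel spacing.
    """

    spheroid_radius: float = 55.0
    voxel_spacing: tuple = (1.0, 0.5, 0.5)
    channel_set: tuple = ("tumor", "fibroblast", "cd31")
    vessel_params: VesselParams = field(default_factory=VesselParams)
    cell_params: dict = field(default_factory=dict)
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    psf_sigma: float = 0.6
    vessel_intensity: float = 200.0
    body_intensity: dict = field(default_factory=lambda: dict(DEFAULT_BODY_INTENSITY))
    margin: float = 6.0
    stack_shape: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spheroid_radius <= 0:
            raise ConfigurationError("spheroid_radius must be positive")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError("voxel_spacing must be three positive lengths")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if isinstance(self.vessel_params, dict):
            self.vessel_params = VesselParams(**self.vessel_params)
        if isinstance(self.noise_params, dict):
            self.noise_params = NoiseParams(**self.noise_params)
        self.cell_params = {
            role: (cp if isinstance(cp, CellParams) else CellParams(**cp))
            for role, cp in self.cell_params.items()
        }
        rmin, rmax = self.vessel_params.radius_range
        if rmax >= self.spheroid_radius / 4:
            raise ConfigurationError("vessel radii must stay below spheroid_radius / 4")
        for role, cp in self.cell_params.items():
            if cp.orb_diameter / 2 >= self.spheroid_radius:
                raise ConfigurationError(f"{role}: orb larger than spheroid")
        if self.psf_sigma < 0:
            raise ConfigurationError("psf_sigma must be >= 0")

    @property
    def shape(self) -> tuple:
        """Stack shape (Z, Y, X) derived from radius, margin and spacing."""
        if self.stack_shape is not None:
            return tuple(int(s) for s in self.stack_shape)
        extent = 2.0 * (self.spheroid_radius + self.margin)
        return tuple(int(np.ceil(extent / s)) for s in self.voxel_spacing)

    @property
    def center(self) -> np.ndarray:
        """Spheroid centre in µm (centre of the stack)."""
        return (np.array(self.shape) - 1) * np.array(self.voxel_spacing) / 2.0


@dataclass
class Centerline:
    """One traced-vessel ground-truth polyline."""

    points: np.ndarray          # (N, 3) µm, (z, y, x)
    radii: np.ndarray           # (N,) µm
    network_id: int
    depth: int                  # branching depth from the root (root = 0)

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class GroundTruth:
    """Everything the phantom knows about itself."""

    centerlines: list = field(default_factory=list)
    masks: dict = field(default_factory=dict)            # role -> bool (Z, Y, X)
    cell_centroids: dict = field(default_factory=dict)   # role -> (N, 3) µm
    spheroid_mask: np.ndarray | None = None

    @property
    def network_partition(self) -> dict:
        return {i: cl.network_id for i, cl in enumerate(self.centerlines)}

    def total_centerline_length(self) -> float:
        return float(sum(cl.length for cl in self.centerlines))

    def n_networks(self) -> int:
        return len({cl.network_id for cl in self.centerlines})


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _perpendicular_jitter(direction, rng, angle_sd=0.35):
    """New direction: persistence along `direction` plus angular noise."""
    return _unit(direction + rng.normal(scale=angle_sd, size=3))


def generate_vessel_network(spec: PhantomSpec) -> GroundTruth:
    """Grow stochastic branching vessel trees inside the spheroid.

    Each of ``n_roots`` seeds grows a persistent random walk; at every step a
    side branch may be spawned (probability ``branch_prob``) up to
    ``max_depth``.  Growth stops at the spheroid boundary.  Per-point radii
    taper monotonically from root to tip within ``radius_range``.
    Deterministic for a fixed ``spec.seed``.
    """
    vp = spec.vessel_params
    rng = np.random.default_rng(spec.seed)
    center = spec.center
    R = spec.spheroid_radius
    rmin, rmax = vp.radius_range
    truth = GroundTruth()

    # wall margin keeps the rendered tube inside the body
    def inside(p, r):
        return np.linalg.norm(p - center) <= R - r - 0.5

    max_steps = int(np.ceil(3.0 * R / vp.step_length))

    for root in range(vp.n_roots):
        # queue of branches to grow: (start point, direction, start radius, depth)
        start = center + _random_direction(rng) * rng.uniform(0, 0.6 * R)
        queue = [(start, _random_direction(rng), rng.uniform(0.7 * rmax, rmax), 0)]
        while queue:
            p, d, r0, depth = queue.pop(0)
            pts = [p.copy()]
            branch_starts = []
            for _ in range(max_steps):
                d = _perpendicular_jitter(d, rng)
                nxt = pts[-1] + d * vp.step_length
                if not inside(nxt, rmin):
                    break
                pts.append(nxt)
                if depth < vp.max_depth and rng.random() < vp.branch_prob:
                    branch_starts.append((len(pts) - 1, _perpendicular_jitter(d, rng, 1.2)))
            if len(pts) < 2:
                continue
            pts = np.array(pts)
            # taper: linear decay from r0 to max(rmin, 0.6 r0) along the branch
            r_end = max(rmin, 0.6 * r0)
            radii = np.linspace(r0, r_end, len(pts))
            truth.centerlines.append(
                Centerline(points=pts, radii=radii, network_id=root, depth=depth)
            )
            for idx, bdir in branch_starts:
                child_r0 = max(rmin, radii[idx] * rng.uniform(0.6, 0.9))
                queue.append((pts[idx].copy(), bdir, child_r0, depth + 1))
    return truth


def _place_cells(spec, cp, rng, occupied):
    """Rejection-sample non-overlapping orb centres inside the spheroid."""
    center = spec.center
    R = spec.spheroid_radius
    r_orb = cp.orb_diameter / 2.0
    r_eff = R - r_orb - 1.0
    pts: list = []
    if cp.placement == "clustered":
        n_seeds = max(1, cp.count // 8)
        seeds = [center + _random_direction(rng) * rng.uniform(0, 0.7 * r_eff)
                 for _ in range(n_seeds)]
    attempts = 0
    while len(pts) < cp.count:
        attempts += 1
        if attempts > 10_000:
            raise ConfigurationError(
                f"could not place {cp.count} non-overlapping orbs "
                f"(placed {len(pts)}) after 10000 attempts"
            )
        if cp.placement == "uniform":
            p = center + _random_direction(rng) * r_eff * rng.random() ** (1 / 3)
        elif cp.placement == "shell":
            p = center + _random_direction(rng) * rng.uniform(0.75, 1.0) * r_eff
        else:  # clustered
            seed = seeds[rng.integers(len(seeds))]
            p = seed + rng.normal(scale=cp.orb_diameter, size=3)
            if np.linalg.norm(p - center) > r_eff:
                continue
        sep = max(cp.min_separation, cp.orb_diameter)
        if any(np.linalg.norm(p - q) < sep for q in pts):
            continue
        if any(np.linalg.norm(p - q) < (r_orb + orad) for q, orad in occupied):
            continue
        pts.append(p)
    occupied.extend((p, r_orb) for p in pts)
    return np.array(pts) if pts else np.empty((0, 3))


def _stamp_ball(volume, center_um, radius_um, spacing, value):
    """Set voxels within radius_um of center_um (anisotropic grid) to >= value."""
    spacing = np.asarray(spacing)
    lo = np.maximum(np.floor((center_um - radius_um) / spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil((center_um + radius_um) / spacing).astype(int) + 1, volume.shape
    )
    if np.any(lo >= hi):
        return False
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = sum(((g * s - c) ** 2 for g, s, c in zip(grids, spacing, center_um)))
    sub = volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(sub, np.where(d2 <= radius_um**2, value, 0), out=sub)
    clipped = (
        np.any((center_um - radius_um) < -spacing / 2)
        or np.any((center_um + radius_um) > (np.array(volume.shape) - 0.5) * spacing)
    )
    return clipped


def _render_tube(volume, centerline, spacing, value):
    """Rasterize a polyline with per-point radii as a tube of balls."""
    step = min(spacing) * 0.5
    clipped = False
    pts, radii = centerline.points, centerline.radii
    for i in range(len(pts) - 1):
        seg = pts[i + 1] - pts[i]
        seglen = np.linalg.norm(seg)
        n_sub = max(1, int(np.ceil(seglen / step)))
        for t in np.linspace(0.0, 1.0, n_sub + 1):
            p = pts[i] + t * seg
            r = radii[i] + t * (radii[i + 1] - radii[i])
            clipped |= _stamp_ball(volume, p, r, spacing, value)
    return clipped


def _sphere_mask(shape, spacing, center, radius):
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = sum(((g * s - c) ** 2 for g, s, c in zip(grids, spacing, center)))
    return d2 <= radius**2


def rasterize_phantom(
    spec: PhantomSpec, truth: GroundTruth | None = None
) -> tuple[MultichannelStack, GroundTruth]:
    """Render a spec (and optionally pre-grown centerlines) into a stack.

    Vessels become tubes of local radius in the CD31 channel; each cell
    population becomes orbs in its channel; the tumor and fibroblast
    channels additionally carry a diffuse body texture so the combined
    channel delineates the VTS body.  A Gaussian PSF and
    Poisson + Gaussian + offset noise are applied to the rendered
    intensities; the returned ground truth carries the noiseless binary
    masks.
    """
    if truth is None:
        truth = generate_vessel_network(spec) if "cd31" in spec.channel_set else GroundTruth()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    spacing = np.array(spec.voxel_spacing)
    shape = spec.shape
    body = _sphere_mask(shape, spacing, spec.center, spec.spheroid_radius)
    truth.spheroid_mask = body

    occupied: list = []
    channels = []
    roles = {}
    noise = spec.noise_params
    for ci, role in enumerate(spec.channel_set):
        clean = np.zeros(shape, dtype=np.float32)
        mask_parts = np.zeros(shape, dtype=bool)
        if role == "cd31":
            for cl in truth.centerlines:
                if _render_tube(clean, cl, spacing, spec.vessel_intensity):
                    log.warning("vessel tube clipped at stack bounds")
            mask_parts |= clean > 0
        if role in spec.body_intensity:
            clean[body] = np.maximum(clean[body], spec.body_intensity[role])
            mask_parts |= body
        cp = spec.cell_params.get(role)
        if cp is not None and cp.count > 0:
            pts = _place_cells(spec, cp, rng, occupied)
            truth.cell_centroids[role] = pts
            orb = np.zeros(shape, dtype=np.float32)
            for p in pts:
                if _stamp_ball(orb, p, cp.orb_diameter / 2.0, spacing, cp.intensity):
                    log.warning("%s orb clipped at stack bounds", role)
            mask_parts |= orb > 0
            np.maximum(clean, orb, out=clean)
        elif cp is not None:
            truth.cell_centroids[role] = np.empty((0, 3))
        truth.masks[role] = mask_parts
        # optics + noise
        img = clean
        if spec.psf_sigma > 0:
            img = ndimage.gaussian_filter(img, sigma=spec.psf_sigma / spacing)
        if noise.photon_scale > 0:
            img = rng.poisson(img * noise.photon_scale).astype(np.float32) / noise.photon_scale
        img = img + noise.background_level
        if noise.gaussian_sd > 0:
            img = img + rng.normal(scale=noise.gaussian_sd, size=shape).astype(np.float32)
        channels.append(np.clip(img, 0, None).astype(np.float32))
        roles[ci] = role

    stack = MultichannelStack(np.stack(channels), tuple(spacing), roles)
    return stack, truth


def generate_phantom(spec: PhantomSpec) -> tuple[MultichannelStack, GroundTruth]:
    """Convenience: grow vessels (if a CD31 channel is requested) and render."""
    return rasterize_phantom(spec)


# ---------------------------------------------------------------------------
# synthetic treated/control ratio tables for the VEI calibration
# ---------------------------------------------------------------------------

RATIO_COLUMNS = ("rV", "rSI", "rSN")


def generate_ranking_dataset(
    n_groups: int,
    model=None,
    noise_sd: float = 0.02,
    seed: int = 0,
    ratio_range: tuple = (0.25, 4.0),
    clip: bool = False,
) -> pd.DataFrame:
    """Synthetic treatment-group table for exercising the VEI calibration.

    Each row is one treatment group with treated/control ratios of PV volume
    (rV), supply index (rSI) and segments-per-network (rSN), drawn
    log-uniformly from ``ratio_range``, plus an emulated observer score
    ``os`` = VEI(model, ratios) + Gaussian(0, noise_sd).  With ``clip=True``
    the score is clipped to the [-1, +1] observer scale (note clipping
    breaks the exact os == VEI identity for strong effects).
    """
    from .ranking import VEIModel, reference_model

    if n_groups < 6:
        raise ConfigurationError(
            "n_groups must be >= 6 (the model has six free parameters)"
        )
    if model is None:
        model = reference_model()
    if not isinstance(model, VEIModel):
        raise TypeError("model must be a VEIModel")
    if not (np.all(np.isfinite(model.weights_)) and np.all(model.exponents_ > 0)):
        raise ConfigurationError("model must have finite weights and positive exponents")
    rng = np.random.default_rng(seed)
    lo, hi = np.log(ratio_range[0]), np.log(ratio_range[1])
    ratios = np.exp(rng.uniform(lo, hi, size=(n_groups, 3)))
    os_clean = model.predict(ratios)
    os = os_clean + (rng.normal(scale=noise_sd, size=n_groups) if noise_sd > 0 else 0.0)
    if clip:
        os = np.clip(os, -1.0, 1.0)
    df = pd.DataFrame(ratios, columns=list(RATIO_COLUMNS))
    df.insert(0, "group", [f"G{i:03d}" for i in range(n_groups)])
    df["os"] = os
    return df


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def save_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    """Write centerlines/centroids as JSON and masks as uncompressed TIFF."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "centerlines": [
            {
                "network_id": cl.network_id,
                "depth": cl.depth,
                "points_um": cl.points.tolist(),
                "radii_um": cl.radii.tolist(),
            }
            for cl in truth.centerlines
        ],
        "cell_centroids_um": {k: v.tolist() for k, v in truth.cell_centroids.items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(payload))
    for role, mask in truth.masks.items():
        tifffile.imwrite(out / f"mask_{role}.tif", mask.astype(np.uint8))
    if truth.spheroid_mask is not None:
        tifffile.imwrite(out / "mask_vts.tif", truth.spheroid_mask.astype(np.uint8))
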