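"""Shared fixtures: small seeded phantoms and geometric masks.

Heavy phantom pipelines are session-scoped so several test modules can
share one render.
"""

from __future__ import annotations

import numpy as np
import pytest

from vtscope import (
    CellParams,
    PhantomSpec,
    PipelineConfig,
    generate_phantom,
    median_filter_3d,
    vts_surface_mask,
    with_combined_channel,
)

SPACING = (1.0, 0.5, 0.5)


def tube_mask(shape, p0, p1, radius, spacing=SPACING):
    """Voxelized cylinder (capsule) between two points given in µm."""
    grids = np.meshgrid(
        *[np.arange(s) * sp for s, sp in zip(shape, spacing)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    t = np.clip(((pts - p0) @ d) / (d @ d), 0.0, 1.0)
    proj = p0 + t[..., None] * d
    return np.linalg.norm(pts - proj, axis=-1) <= radius


def sphere_mask(shape, center, radius, spacing=SPACING):
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = sum(((g * s - c) ** 2 for g, s, c in zip(grids, spacing, center)))
    return d2 <= radius**2


@pytest.fixture(scope="session")
def small_phantom():
    """A 30 µm-radius three-channel phantom with 10 orbs per population."""
    spec = PhantomSpec(
        spheroid_radius=30.0,
        margin=5.0,
        channel_set=("tumor", "fibroblast", "cd31"),
        cell_params={
            "tumor": CellParams(count=10),
            "fibroblast": CellParams(count=10),
        },
        seed=3,
    )
    stack, truth = generate_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def small_pipeline(small_phantom):
    """The small phantom after filtering, with combined channel and VTS mask."""
    spec, stack, truth = small_phantom
    filtered = with_combined_channel(median_filter_3d(stack))
    vts, vts_volume = vts_surface_mask(filtered)
    return spec, filtered, truth, vts, vts_volume


@pytest.fixture
def config():
    return PipelineConfig()
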