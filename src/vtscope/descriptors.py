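"""Per-VTS multiparametric descriptor assembly.

One analysed spheroid becomes one row of named, unit-annotated
parameters drawn from a versioned registry.  With the full staining
panel (tumor, fibroblast, CD31, CD11b, Col IV, Hif1a) the registry
defines exactly 71 parameters; the three-cellular-channel configuration
yields the 46-parameter core used for cross-experiment reproducibility
analyses.  Families whose required channels are absent are dropped as a
whole (logged), never silently filled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, ConfigurationError
from .imgio import MultichannelStack
from . import preprocess, segment, vasctrace, distfield

log = logging.getLogger(__name__)

REGISTRY_VERSION = "1.0"

_META_COLUMNS = ("sample", "group", "experiment", "registry_version")


@dataclass(frozen=True)
class Parameter:
    name: str
    family: str
    units: str
    requires: tuple
    provenance: str


def _p(name, family, units, requires, provenance):
    return Parameter(name, family, units, tuple(requires), provenance)


_CELLULAR = ("tumor", "fibroblast", "cd31")

#: The full parameter registry.  The core families (size, composition,
#: tumor/fibroblast cell statistics, PV network, distance field) need the
#: three cellular channels and total 46 parameters; the macrophage, ECM and
#: hypoxia families add 25 more for the full six-channel panel (71 total).
REGISTRY: tuple = tuple(
    [
        # --- size (2) ---
        _p("vts_volume_um3", "size", "um^3", (), "vts_surface_mask"),
        _p("vts_equiv_diameter_um", "size", "um", (), "vts_surface_mask"),
        # --- composition (9) ---
        *[
            _p(f"abs_volume_{r}_um3", "composition", "um^3", _CELLULAR, "segment_channel")
            for r in _CELLULAR
        ],
        *[
            _p(f"rel_volume_{r}", "composition", "fraction", _CELLULAR, "segment_channel")
            for r in _CELLULAR
        ],
        *[
            _p(f"comp_fraction_{r}", "composition", "fraction", _CELLULAR, "segment_channel")
            for r in _CELLULAR
        ],
        # --- cell statistics (2 x 5) ---
        *[
            p
            for role, other in (("tumor", "fibroblast"), ("fibroblast", "tumor"))
            for p in (
                _p(f"{role}_cell_count", "cells", "count", _CELLULAR, "detect_cells"),
                _p(f"{role}_cell_density_per_mm3", "cells", "1/mm^3", _CELLULAR, "detect_cells"),
                _p(f"{role}_median_dist_pv_um", "cells", "um", _CELLULAR, "cell_distances"),
                _p(f"{role}_median_dist_surface_um", "cells", "um", _CELLULAR, "cell_distances"),
                _p(
                    f"{role}_median_dist_{other}_um",
                    "cells",
                    "um",
                    _CELLULAR,
                    "complementary_cell_distances",
                ),
            )
        ],
        # --- PV network (19) ---
        _p("pv_n_networks", "pv_network", "count", _CELLULAR, "network_stats"),
        _p("pv_n_segments", "pv_network", "count", _CELLULAR, "network_stats"),
        _p("pv_segments_per_network", "pv_network", "count", _CELLULAR, "network_stats"),
        _p("pv_total_length_um", "pv_network", "um", _CELLULAR, "network_stats"),
        _p("pv_mean_segment_length_um", "pv_network", "um", _CELLULAR, "network_stats"),
        *[
            _p(f"pv_diameter_{s}_um", "pv_network", "um", _CELLULAR, "segment_diameters")
            for s in ("mean", "median", "sd", "max", "q25", "q75")
        ],
        *[
            _p(f"pv_branch_level_{s}", "pv_network", "level", _CELLULAR, "branch_levels")
            for s in ("mean", "median", "max")
        ],
        *[
            _p(f"pv_network_volume_{s}_um3", "pv_network", "um^3", _CELLULAR, "network_stats")
            for s in ("mean", "median", "max")
        ],
        *[
            _p(f"pv_network_length_{s}_um", "pv_network", "um", _CELLULAR, "network_stats")
            for s in ("mean", "max")
        ],
        # --- distance field (6) ---
        *[
            _p(f"pv_dist_{s}_um", "distance_field", "um", _CELLULAR, "pv_distance_field")
            for s in ("mean", "median", "q25", "q75", "max")
        ],
        _p("pv_supply_index", "distance_field", "", _CELLULAR, "supply_index"),
        # --- macrophages (10) ---
        _p("cd11b_cell_count", "macrophage", "count", ("cd11b",), "detect_cells"),
        _p("cd11b_cell_density_per_mm3", "macrophage", "1/mm^3", ("cd11b",), "detect_cells"),
        _p("rel_volume_cd11b", "macrophage", "fraction", ("cd11b",), "segment_channel"),
        _p("cd11b_median_dist_pv_um", "macrophage", "um", ("cd11b", "cd31"), "cell_distances"),
        _p("cd11b_mean_dist_pv_um", "macrophage", "um", ("cd11b", "cd31"), "cell_distances"),
        _p("cd11b_median_dist_surface_um", "macrophage", "um", ("cd11b",), "cell_distances"),
        _p("cd11b_n_aggregates", "macrophage", "count", ("cd11b",), "object_volume_distribution"),
        *[
            _p(
                f"cd11b_aggregate_volume_{s}_um3",
                "macrophage",
                "um^3",
                ("cd11b",),
                "object_volume_distribution",
            )
            for s in ("median", "max", "total")
        ],
        # --- ECM / Col IV (8) ---
        _p("abs_volume_colIV_um3", "ecm", "um^3", ("colIV",), "segment_channel"),
        _p("rel_volume_colIV", "ecm", "fraction", ("colIV",), "segment_channel"),
        _p("colIV_pv_associated_fraction", "ecm", "fraction", ("colIV", "cd31"), "colIV_association"),
        _p("colIV_associated_over_cd31", "ecm", "ratio", ("colIV", "cd31"), "colIV_association"),
        _p(
            "colIV_in_vts_nonassociated_fraction",
            "ecm",
            "fraction",
            ("colIV", "cd31"),
            "colIV_association",
        ),
        _p("colIV_outside_vts_fraction", "ecm", "fraction", ("colIV", "cd31"), "colIV_association"),
        _p("colIV_n_objects", "ecm", "count", ("colIV",), "segment_channel"),
        _p("colIV_largest_object_um3", "ecm", "um^3", ("colIV",), "object_volume_distribution"),
        # --- hypoxia (7) ---
        _p("hif1a_cell_count", "hypoxia", "count", ("hif1a",), "detect_cells"),
        _p("hif1a_cell_density_per_mm3", "hypoxia", "1/mm^3", ("hif1a",), "detect_cells"),
        _p("hif1a_median_dist_pv_um", "hypoxia", "um", ("hif1a", "cd31"), "cell_distances"),
        _p("hif1a_mean_dist_pv_um", "hypoxia", "um", ("hif1a", "cd31"), "cell_distances"),
        _p("hif1a_median_dist_surface_um", "hypoxia", "um", ("hif1a",), "cell_distances"),
        _p("hif1a_max_dist_pv_um", "hypoxia", "um", ("hif1a", "cd31"), "cell_distances"),
        _p("hif1a_far_fraction", "hypoxia", "fraction", ("hif1a", "cd31"), "cell_distances"),
    ]
)

assert len(REGISTRY) == 71, "registry cardinality contract"
assert len({p.name for p in REGISTRY}) == 71, "registry names must be unique"


def registry_parameters(present_roles) -> list:
    """Registry entries whose required channels are all present."""
    present = set(present_roles)
    return [p for p in REGISTRY if set(p.requires) <= present]


def registry_as_json() -> str:
    return json.dumps(
        {
            "version": REGISTRY_VERSION,
            "parameters": [
                {
                    "name": p.name,
                    "family": p.family,
                    "units": p.units,
                    "requires": list(p.requires),
                    "provenance": p.provenance,
                }
                for p in REGISTRY
            ],
        },
        indent=1,
    )


def _nanstats(values, prefix, suffix="_um"):
    """mean/median/sd/max/q25/q75 helpers over a possibly-empty vector."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    out = {}
    stats = {
        "mean": np.mean,
        "median": np.median,
        "sd": lambda x: np.std(x, ddof=1) if len(x) > 1 else 0.0,
        "max": np.max,
        "q25": lambda x: np.quantile(x, 0.25),
        "q75": lambda x: np.quantile(x, 0.75),
    }
    for key, fn in stats.items():
        out[f"{prefix}{key}{suffix}"] = float(fn(v)) if v.size else np.nan
    return out


def compute_descriptors(
    stack: MultichannelStack,
    config: PipelineConfig | None = None,
    sample: str = "vts",
    group: str = "",
    experiment: str = "",
) -> pd.DataFrame:
    """Run the full pipeline on one stack and return a one-row table.

    The row contains every registry parameter whose required channels are
    present in the stack; with the three cellular channels that is the
    46-parameter core, with the full panel exactly 71.  Deterministic for
    a given stack and configuration.
    """
    config = config or PipelineConfig()
    roles = set(stack.channel_roles.values())
    required_missing = set(_CELLULAR) - roles
    if required_missing:
        msg = f"missing required cellular channels: {sorted(required_missing)}"
        if config.strict:
            raise ConfigurationError(msg)
        log.warning(msg)

    filtered = preprocess.median_filter_3d(stack, config=config)
    filtered = preprocess.with_combined_channel(filtered)
    vts_mask, vts_volume = preprocess.vts_surface_mask(filtered, config)
    voxel_vol = stack.voxel_volume
    values: dict = {}

    values["vts_volume_um3"] = vts_volume
    values["vts_equiv_diameter_um"] = 2.0 * (3.0 * vts_volume / (4.0 * np.pi)) ** (1.0 / 3.0)

    segs: dict = {}
    cells: dict = {}
    for role in ("tumor", "fibroblast", "cd31", "cd11b", "colIV", "hif1a"):
        if role in roles:
            segs[role] = segment.segment_channel(filtered, role, config, vts_mask)
    for role in ("tumor", "fibroblast", "cd11b", "hif1a"):
        if role in roles:
            cells[role] = segment.detect_cells(filtered, role, config, vts_mask)

    if not set(_CELLULAR) - roles:
        rels = {}
        for r in _CELLULAR:
            vol = float((segs[r].mask & vts_mask).sum()) * voxel_vol
            rel = vol / vts_volume if vts_volume else np.nan
            values[f"abs_volume_{r}_um3"] = vol
            values[f"rel_volume_{r}"] = rel
            rels[r] = rel
        total = sum(rels.values())
        for r in _CELLULAR:
            values[f"comp_fraction_{r}"] = rels[r] / total if total else np.nan

        cd31_mask = segs["cd31"].mask
        graph, net_stats = vasctrace.trace_vessels(cd31_mask, stack.spacing, config)
        values["pv_n_networks"] = net_stats.attrs["n_networks"]
        values["pv_n_segments"] = net_stats.attrs["n_segments"]
        values["pv_segments_per_network"] = net_stats.attrs["segments_per_network"]
        values["pv_total_length_um"] = net_stats.attrs["total_length_um"]
        seg_lengths = [s.length for s in graph.segments]
        values["pv_mean_segment_length_um"] = (
            float(np.mean(seg_lengths)) if seg_lengths else np.nan
        )
        values.update(_nanstats([s.mean_diameter for s in graph.segments], "pv_diameter_"))
        levels = [s.branch_level for s in graph.segments]
        lv = _nanstats(levels, "pv_branch_level_", suffix="")
        values.update({k: lv[k] for k in ("pv_branch_level_mean", "pv_branch_level_median", "pv_branch_level_max")})
        nv = _nanstats(net_stats["volume_um3"], "pv_network_volume_", suffix="_um3")
        values.update({k: nv[k] for k in ("pv_network_volume_mean_um3", "pv_network_volume_median_um3", "pv_network_volume_max_um3")})
        nl = _nanstats(net_stats["length_um"], "pv_network_length_")
        values.update({k: nl[k] for k in ("pv_network_length_mean_um", "pv_network_length_max_um")})

        field = distfield.pv_distance_field(cd31_mask, vts_mask, stack.spacing)
        fv = _nanstats(field.finite_values(), "pv_dist_")
        values.update({k: fv[k] for k in ("pv_dist_mean_um", "pv_dist_median_um", "pv_dist_q25_um", "pv_dist_q75_um", "pv_dist_max_um")})
        rel_cd31_pct = 100.0 * values["rel_volume_cd31"]
        median_d = values["pv_dist_median_um"]
        values["pv_supply_index"] = (
            distfield.supply_index(rel_cd31_pct, median_d)
            if rel_cd31_pct > 0 and np.isfinite(median_d) and median_d > 0
            else np.nan
        )

        for role, other in (("tumor", "fibroblast"), ("fibroblast", "tumor")):
            cs = cells[role]
            values[f"{role}_cell_count"] = cs.count
            values[f"{role}_cell_density_per_mm3"] = cs.density(vts_volume)
            values[f"{role}_median_dist_pv_um"] = distfield.cell_distances(
                cs, cd31_mask, stack.spacing, mode="mask"
            ).attrs["median_um"]
            values[f"{role}_median_dist_surface_um"] = distfield.cell_distances(
                cs, vts_mask, stack.spacing, mode="surface"
            ).attrs["median_um"]
            values[f"{role}_median_dist_{other}_um"] = (
                distfield.complementary_cell_distances(cs, cells[other]).attrs["median_um"]
            )
    else:
        cd31_mask = segs["cd31"].mask if "cd31" in segs else None
        field = None

    if "cd11b" in roles:
        cs = cells["cd11b"]
        values["cd11b_cell_count"] = cs.count
        values["cd11b_cell_density_per_mm3"] = cs.density(vts_volume)
        values["rel_volume_cd11b"] = segment.relative_volume(segs["cd11b"], vts_mask)
        if cd31_mask is not None:
            dpv = distfield.cell_distances(cs, cd31_mask, stack.spacing, mode="mask")
            values["cd11b_median_dist_pv_um"] = dpv.attrs["median_um"]
            values["cd11b_mean_dist_pv_um"] = (
                float(dpv["distance_um"].mean()) if len(dpv) else np.nan
            )
        values["cd11b_median_dist_surface_um"] = distfield.cell_distances(
            cs, vts_mask, stack.spacing, mode="surface"
        ).attrs["median_um"]
        agg = segment.object_volume_distribution(segs["cd11b"])
        values["cd11b_n_aggregates"] = agg.attrs["n"]
        values["cd11b_aggregate_volume_median_um3"] = agg.attrs["median"]
        values["cd11b_aggregate_volume_max_um3"] = agg.attrs["max"]
        values["cd11b_aggregate_volume_total_um3"] = (
            float(agg["volume_um3"].sum()) if len(agg) else 0.0
        )

    if "colIV" in roles:
        cseg = segs["colIV"]
        vol = float((cseg.mask & vts_mask).sum()) * voxel_vol
        values["abs_volume_colIV_um3"] = vol
        values["rel_volume_colIV"] = vol / vts_volume if vts_volume else np.nan
        values["colIV_n_objects"] = cseg.n_objects
        obj = segment.object_volume_distribution(cseg)
        values["colIV_largest_object_um3"] = obj.attrs["max"]
        if cd31_mask is not None:
            assoc = distfield.colIV_association(
                cseg.mask,
                cd31_mask,
                vts_mask,
                d_assoc=config.colIV_association_distance,
                spacing=stack.spacing,
            )
            values["colIV_pv_associated_fraction"] = assoc["associated_fraction"]
            values["colIV_associated_over_cd31"] = assoc["associated_over_cd31"]
            values["colIV_in_vts_nonassociated_fraction"] = assoc[
                "in_vts_nonassociated_fraction"
            ]
            values["colIV_outside_vts_fraction"] = assoc["outside_vts_fraction"]

    if "hif1a" in roles:
        cs = cells["hif1a"]
        values["hif1a_cell_count"] = cs.count
        values["hif1a_cell_density_per_mm3"] = cs.density(vts_volume)
        values["hif1a_median_dist_surface_um"] = distfield.cell_distances(
            cs, vts_mask, stack.spacing, mode="surface"
        ).attrs["median_um"]
        if cd31_mask is not None:
            dpv = distfield.cell_distances(cs, cd31_mask, stack.spacing, mode="mask")
            values["hif1a_median_dist_pv_um"] = dpv.attrs["median_um"]
            d = dpv["distance_um"].to_numpy(dtype=float)
            values["hif1a_mean_dist_pv_um"] = float(d.mean()) if d.size else np.nan
            values["hif1a_max_dist_pv_um"] = float(d.max()) if d.size else np.nan
            ref = values.get("pv_dist_median_um", np.nan)
            values["hif1a_far_fraction"] = (
                float((d > ref).mean()) if d.size and np.isfinite(ref) else np.nan
            )

    expected = registry_parameters(roles)
    row = {name: values.get(name, np.nan) for name in (p.name for p in expected)}
    dropped = [p.family for p in REGISTRY if p not in expected]
    if dropped:
        log.info("omitted parameter families (missing channels): %s", sorted(set(dropped)))
    out = pd.DataFrame([row])
    out.insert(0, "sample", sample)
    out.insert(1, "group", group)
    out.insert(2, "experiment", experiment)
    out.insert(3, "registry_version", REGISTRY_VERSION)
    return out


def parameter_columns(table: pd.DataFrame) -> list:
    """Names of the registry-parameter columns of a descriptor table."""
    return [c for c in table.columns if c not in _META_COLUMNS]


def pool_descriptors(rows, strict: bool = True) -> pd.DataFrame:
    """Stack per-VTS rows into one long-form table.

    In strict mode all rows must share the registry version and the exact
    parameter set (mixing 71- and 46-parameter rows raises).
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to pool")
    first_cols = list(rows[0].columns)
    for r in rows[1:]:
        if r["registry_version"].iloc[0] != rows[0]["registry_version"].iloc[0]:
            raise ValueError("registry version mismatch between rows")
        if strict and list(r.columns) != first_cols:
            raise ValueError("parameter-set mismatch between rows (strict mode)")
    return pd.concat(rows, ignore_index=True)


def save_registry(path: str | Path) -> None:
    Path(path).write_text(registry_as_json())
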