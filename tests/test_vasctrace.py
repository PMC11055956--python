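"""Vessel tracing: skeleton graph, diameters, branch levels, network stats."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.distance import cdist

from vtscope import (
    branch_levels,
    network_stats,
    segment_diameters,
    skeletonize_and_graph,
    trace_vessels,
)
from vtscope.vasctrace import VesselGraph, VesselSegment
from conftest import tube_mask, SPACING


class TestSkeletonGraph:
    def test_straight_tube_single_segment(self):
        shape = (24, 40, 240)
        mask = tube_mask(shape, (12, 10, 8), (12, 10, 108), 4.0)
        graph = skeletonize_and_graph(mask, SPACING)
        assert graph.n_networks == 1
        assert graph.n_segments == 1
        assert graph.total_length() == pytest.approx(100.0, abs=2 * 0.5)

    def test_y_phantom_topology(self):
        shape = (30, 240, 240)
        c = (15, 60, 60)
        mask = (
            tube_mask(shape, c, (15, 60, 160), 3.0)
            | tube_mask(shape, c, (15, 150, 60), 3.0)
            | tube_mask(shape, c, (15, 20, 60), 3.0)
        )
        graph = skeletonize_and_graph(mask, SPACING)
        assert graph.n_networks == 1
        assert graph.n_segments == 3
        degrees = sorted(n["degree"] for n in graph.nodes.values())
        assert degrees == [1, 1, 1, 3]

    def test_empty_mask_empty_graph(self):
        graph = skeletonize_and_graph(np.zeros((8, 8, 8), bool), SPACING)
        assert graph.n_networks == 0 and graph.n_segments == 0

    def test_prune_length_zero_is_identity(self):
        shape = (30, 240, 240)
        c = (15, 60, 60)
        mask = (
            tube_mask(shape, c, (15, 60, 160), 3.0)
            | tube_mask(shape, c, (15, 150, 60), 3.0)
            | tube_mask(shape, c, (15, 20, 60), 3.0)
        )
        a = skeletonize_and_graph(mask, SPACING, prune_length=0.0)
        b = skeletonize_and_graph(mask, SPACING, prune_length=0.0)
        assert a.n_segments == b.n_segments

    def test_axis_permutation_invariance_isotropic(self):
        shape = (60, 60, 60)
        c = (30, 30, 30)
        mask = (
            tube_mask(shape, c, (30, 30, 55), 2.5, spacing=(1, 1, 1))
            | tube_mask(shape, c, (30, 55, 30), 2.5, spacing=(1, 1, 1))
            | tube_mask(shape, c, (55, 30, 30), 2.5, spacing=(1, 1, 1))
        )
        base = skeletonize_and_graph(mask, (1, 1, 1))
        for perm in ((1, 0, 2), (2, 1, 0), (0, 2, 1)):
            g = skeletonize_and_graph(mask.transpose(perm), (1, 1, 1))
            assert g.n_networks == base.n_networks
            assert g.n_segments == base.n_segments
            assert g.total_length() == pytest.approx(base.total_length(), rel=0.05)


class TestDiameters:
    def test_cylinder_diameter_analytic(self):
        shape = (24, 40, 240)
        mask = tube_mask(shape, (12, 10, 8), (12, 10, 108), 4.0)
        graph = skeletonize_and_graph(mask, SPACING)
        segment_diameters(graph, mask)
        assert graph.segments[0].mean_diameter == pytest.approx(8.0, abs=0.5)

    def test_dilation_increases_diameters(self):
        from scipy import ndimage

        shape = (24, 40, 160)
        mask = tube_mask(shape, (12, 10, 8), (12, 10, 70), 3.0)
        graph = skeletonize_and_graph(mask, SPACING)
        segment_diameters(graph, mask)
        before = [s.mean_diameter for s in graph.segments]
        dilated = ndimage.binary_dilation(mask)
        graph2 = skeletonize_and_graph(mask, SPACING)  # same skeleton
        segment_diameters(graph2, dilated)
        after = [s.mean_diameter for s in graph2.segments]
        assert all(b > a for a, b in zip(before, after))

    def test_point_radii_match_brute_force(self):
        rng = np.random.default_rng(0)
        shape = (32, 32, 32)
        p0 = rng.uniform(8, 12, 3)
        p1 = rng.uniform(20, 26, 3)
        mask = tube_mask(shape, p0, p1, 3.0, spacing=(1, 1, 1))
        graph = skeletonize_and_graph(mask, (1, 1, 1))
        segment_diameters(graph, mask)
        background = np.argwhere(~mask).astype(float)
        for seg in graph.segments:
            brute = cdist(seg.path_voxels.astype(float), background).min(axis=1)
            assert 2 * brute.mean() == pytest.approx(seg.mean_diameter, rel=1e-9)


def random_tree_graph(rng, n_segments):
    """Abstract random tree as a VesselGraph (no voxel paths needed)."""
    graph = VesselGraph(spacing=(1, 1, 1), shape=(1, 1, 1))
    graph.nodes[0] = {"pos": np.zeros(3), "degree": 0, "voxels": np.zeros((1, 3), int)}
    for sid in range(n_segments):
        parent = int(rng.integers(0, sid + 1))
        child = sid + 1
        graph.nodes[child] = {
            "pos": rng.normal(size=3),
            "degree": 0,
            "voxels": np.zeros((1, 3), int),
        }
        length = float(rng.uniform(1.0, 10.0))
        graph.segments.append(
            VesselSegment(
                id=sid,
                network_id=0,
                path=np.zeros((2, 3)),
                path_voxels=np.zeros((2, 3), int),
                nodes=(parent, child),
                length=length,
            )
        )
        graph.nodes[parent]["degree"] += 1
        graph.nodes[child]["degree"] += 1
    return graph


def oracle_branch_levels(graph):
    """Exhaustive oracle: enumerate all endpoint pairs, then recurse levels."""
    g = nx.Graph()
    for s in graph.segments:
        g.add_edge(*s.nodes, sid=s.id, length=s.length)
    leaves = sorted(n for n in g.nodes if g.degree(n) == 1)
    best = (-1.0, None, None)
    for a, b in itertools.combinations(leaves, 2):
        path = nx.shortest_path(g, a, b)  # unique in a tree
        length = sum(g.edges[u, v]["length"] for u, v in zip(path, path[1:]))
        if length > best[0] + 1e-12:
            best = (length, (a, b), path)
    main_path = best[2]
    levels = {}
    main_edges = set(zip(main_path, main_path[1:])) | set(
        zip(main_path[1:], main_path)
    )
    for u, v in g.edges:
        if (u, v) in main_edges:
            levels[g.edges[u, v]["sid"]] = 0

    def assign(node, level):
        for m in g.neighbors(node):
            sid = g.edges[node, m]["sid"]
            if sid in levels:
                continue
            levels[sid] = level + 1
            assign(m, level + 1)

    for n in main_path:
        assign(n, 0)
    return levels


class TestBranchLevels:
    def test_single_segment_is_main_branch(self):
        shape = (24, 40, 160)
        mask = tube_mask(shape, (12, 10, 8), (12, 10, 70), 3.0)
        graph = trace_vessels(mask, SPACING)[0]
        assert [s.branch_level for s in graph.segments] == [0]

    def test_y_phantom_levels(self):
        shape = (30, 240, 240)
        c = (15, 60, 60)
        mask = (
            tube_mask(shape, c, (15, 60, 160), 3.0)   # 100 um leg
            | tube_mask(shape, c, (15, 150, 60), 3.0)  # 90 um leg
            | tube_mask(shape, c, (15, 20, 60), 3.0)   # 40 um leg
        )
        graph = skeletonize_and_graph(mask, SPACING)
        branch_levels(graph)
        by_length = sorted(graph.segments, key=lambda s: s.length)
        assert by_length[0].branch_level == 1     # the 40 um leg
        assert by_length[1].branch_level == 0
        assert by_length[2].branch_level == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_random_trees_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        graph = random_tree_graph(rng, int(rng.integers(2, 31)))
        branch_levels(graph)
        expected = oracle_branch_levels(graph)
        got = {s.id: s.branch_level for s in graph.segments}
        assert got == expected

    def test_cycle_chord_level(self):
        # triangle: tree keeps the two longest edges, the chord gets level 1
        graph = VesselGraph(spacing=(1, 1, 1), shape=(1, 1, 1))
        for n in range(3):
            graph.nodes[n] = {"pos": np.zeros(3), "degree": 2, "voxels": np.zeros((1, 3), int)}
        for sid, (u, v, ln) in enumerate(((0, 1, 5.0), (1, 2, 4.0), (0, 2, 2.0))):
            graph.segments.append(
                VesselSegment(sid, 0, np.zeros((2, 3)), np.zeros((2, 3), int), (u, v), ln)
            )
        branch_levels(graph)
        levels = {s.id: s.branch_level for s in graph.segments}
        assert levels[0] == 0 and levels[1] == 0 and levels[2] == 1

    def test_level_histogram_sums_to_segment_count(self, small_pipeline):
        spec, filtered, truth, vts, _ = small_pipeline
        from vtscope import segment_channel

        seg = segment_channel(filtered, "cd31", vts_mask=vts)
        graph = trace_vessels(seg.mask, filtered.spacing)[0]
        levels = [s.branch_level for s in graph.segments]
        assert all(lv is not None and 0 <= lv <= graph.n_segments for lv in levels)
        hist = np.bincount(levels) if levels else np.array([])
        assert hist.sum() == graph.n_segments


class TestNetworkStats:
    def test_single_network_gets_all_volume(self):
        shape = (24, 40, 160)
        mask = tube_mask(shape, (12, 10, 8), (12, 10, 70), 3.0)
        graph, stats = trace_vessels(mask, SPACING)
        voxel_vol = float(np.prod(SPACING))
        assert stats["volume_um3"].iloc[0] == pytest.approx(mask.sum() * voxel_vol)

    def test_two_equal_tubes_partition(self):
        shape = (24, 120, 160)
        a = tube_mask(shape, (12, 15, 8), (12, 15, 70), 3.0)
        b = tube_mask(shape, (12, 45, 8), (12, 45, 70), 3.0)
        graph, stats = trace_vessels(a | b, SPACING)
        assert graph.n_networks == 2
        v = stats["volume_um3"].to_numpy()
        assert abs(v[0] - v[1]) / v.max() <= 0.05
        # partition conservation is exact
        voxel_vol = float(np.prod(SPACING))
        assert v.sum() == pytest.approx((a | b).sum() * voxel_vol)

    def test_segment_length_totals_consistent(self, small_pipeline):
        spec, filtered, truth, vts, _ = small_pipeline
        from vtscope import segment_channel

        seg = segment_channel(filtered, "cd31", vts_mask=vts)
        graph, stats = trace_vessels(seg.mask, filtered.spacing)
        assert stats["length_um"].sum() == pytest.approx(graph.total_length())
        assert stats.attrs["n_segments"] == graph.n_segments
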