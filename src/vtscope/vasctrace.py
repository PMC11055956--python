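"""Tracing of pseudovascular networks.

The CD31 foreground mask is thinned to a one-voxel 3D skeleton, the
skeleton voxels assembled into a graph of branch nodes (junctions,
degree >= 3), endpoints (degree 1) and branch-free segments, short spur
segments pruned, per-point vessel radii measured from the anisotropic
Euclidean distance transform, and every segment assigned a branch level —
its hierarchical distance from the longest (main) branch of its connected
network.

All geometry is in µm; skeletonization itself runs on the voxel grid,
which is a documented approximation when dz differs from dx.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .config import PipelineConfig

_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


class TracingError(RuntimeError):
    """Internal inconsistency during vessel tracing."""


@dataclass
class VesselSegment:
    """A maximal branch-free skeleton path between two nodes."""

    id: int
    network_id: int
    path: np.ndarray                     # (N, 3) ordered points, µm
    path_voxels: np.ndarray              # (N, 3) voxel indices
    nodes: tuple                         # (u, v) node ids
    length: float
    mean_diameter: float | None = None
    branch_level: int | None = None


@dataclass
class VesselGraph:
    """Traced skeleton as nodes + segments, partitioned into networks."""

    nodes: dict = field(default_factory=dict)     # id -> {"pos": µm, "degree": int}
    segments: list = field(default_factory=list)
    spacing: tuple = (1.0, 1.0, 1.0)
    shape: tuple | None = None

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def network_ids(self) -> list:
        return sorted({s.network_id for s in self.segments})

    @property
    def n_networks(self) -> int:
        return len(self.network_ids)

    def total_length(self) -> float:
        return float(sum(s.length for s in self.segments))

    def segments_of(self, network_id: int) -> list:
        return [s for s in self.segments if s.network_id == network_id]

    def multigraph(self, network_id: int | None = None) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for nid, attrs in self.nodes.items():
            g.add_node(nid, **attrs)
        for s in self.segments:
            if network_id is None or s.network_id == network_id:
                g.add_edge(*s.nodes, key=s.id, length=s.length, sid=s.id)
        return g

    def to_json(self) -> str:
        """Serialize nodes and segments (paths in µm) for export."""
        import json

        return json.dumps(
            {
                "spacing_um": list(self.spacing),
                "nodes": [
                    {"id": int(nid), "pos_um": [float(x) for x in attrs["pos"]],
                     "degree": int(attrs["degree"])}
                    for nid, attrs in sorted(self.nodes.items())
                ],
                "segments": [
                    {
                        "id": s.id,
                        "network": s.network_id,
                        "nodes": [int(n) for n in s.nodes],
                        "length_um": s.length,
                        "mean_diameter_um": s.mean_diameter,
                        "branch_level": s.branch_level,
                        "path_um": s.path.tolist(),
                    }
                    for s in self.segments
                ],
            }
        )

    def segment_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment": [s.id for s in self.segments],
                "network": [s.network_id for s in self.segments],
                "length_um": [s.length for s in self.segments],
                "mean_diameter_um": [s.mean_diameter for s in self.segments],
                "branch_level": [s.branch_level for s in self.segments],
            }
        )


def _path_length(path_um: np.ndarray) -> float:
    if len(path_um) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(path_um, axis=0), axis=1).sum())


def _extract_graph(skel: np.ndarray, spacing: np.ndarray) -> VesselGraph:
    """Collapse a one-voxel skeleton into nodes and branch-free segments."""
    coords = np.argwhere(skel)
    graph = VesselGraph(spacing=tuple(spacing), shape=skel.shape)
    if len(coords) == 0:
        return graph
    index = {tuple(c): i for i, c in enumerate(coords)}
    nbrs: list = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in _OFFSETS:
            j = index.get(tuple(c + off))
            if j is not None:
                nbrs[i].append(j)
    deg = np.array([len(n) for n in nbrs])

    # node voxels: endpoints, junctions, isolated voxels
    is_node_voxel = deg != 2
    # cluster adjacent junction voxels (degree >= 3) into single nodes
    cluster_of = np.full(len(coords), -1)
    next_node = 0
    for i in np.flatnonzero(deg >= 3):
        if cluster_of[i] != -1:
            continue
        stack_ = [i]
        cluster_of[i] = next_node
        while stack_:
            v = stack_.pop()
            for w in nbrs[v]:
                if deg[w] >= 3 and cluster_of[w] == -1:
                    cluster_of[w] = next_node
                    stack_.append(w)
        next_node += 1
    for i in np.flatnonzero((deg <= 1)):
        cluster_of[i] = next_node
        next_node += 1

    pos_um = coords * spacing
    node_members: dict = {}
    for i in np.flatnonzero(is_node_voxel):
        node_members.setdefault(cluster_of[i], []).append(i)

    segments_raw: dict = {}

    def record(path_idx: list) -> None:
        key = tuple(sorted(path_idx))
        if key not in segments_raw:
            segments_raw[key] = list(path_idx)

    for nid, members in node_members.items():
        for v in members:
            for w in nbrs[v]:
                if is_node_voxel[w] and cluster_of[w] == nid:
                    continue  # intra-cluster adjacency
                if is_node_voxel[w]:
                    record([v, w])
                    continue
                # walk the degree-2 chain
                path = [v, w]
                prev, cur = v, w
                while not is_node_voxel[cur]:
                    nxt = [x for x in nbrs[cur] if x != prev]
                    if len(nxt) != 1:  # pragma: no cover - deg==2 guarantees 1
                        raise TracingError("broken chain during segment walk")
                    prev, cur = cur, nxt[0]
                    path.append(cur)
                record(path)

    # pure cycles: degree-2 voxels not covered by any segment
    covered = np.zeros(len(coords), dtype=bool)
    for path in segments_raw.values():
        covered[path] = True
    for i in np.flatnonzero((deg == 2) & ~covered):
        if covered[i]:
            continue
        path = [i]
        prev, cur = i, nbrs[i][0]
        while cur != i:
            path.append(cur)
            covered[cur] = True
            nxt = [x for x in nbrs[cur] if x != prev]
            prev, cur = cur, nxt[0]
        path.append(i)
        covered[i] = True
        cluster_of[i] = next_node
        is_node_voxel[i] = True
        node_members[next_node] = [i]
        next_node += 1
        record(path)

    # build nodes
    for nid, members in node_members.items():
        graph.nodes[nid] = {
            "pos": pos_um[members].mean(axis=0),
            "degree": 0,
            "voxels": coords[members],
        }
    # deterministic segment ordering
    ordered = sorted(segments_raw.values(), key=lambda p: tuple(sorted(p)))
    for sid, path in enumerate(ordered):
        u, v = cluster_of[path[0]], cluster_of[path[-1]]
        seg = VesselSegment(
            id=sid,
            network_id=-1,
            path=pos_um[path],
            path_voxels=coords[path],
            nodes=(int(u), int(v)),
            length=_path_length(pos_um[path]),
        )
        graph.segments.append(seg)
        graph.nodes[u]["degree"] += 1
        graph.nodes[v]["degree"] += 1

    _assign_networks(graph)
    return graph


def _assign_networks(graph: VesselGraph) -> None:
    g = graph.multigraph()
    comps = sorted(nx.connected_components(g), key=min)
    node_net = {}
    for net_id, comp in enumerate(c for c in comps):
        for n in comp:
            node_net[n] = net_id
    # keep only components that carry segments; renumber densely
    used = sorted({node_net[s.nodes[0]] for s in graph.segments})
    renum = {old: new for new, old in enumerate(used)}
    for s in graph.segments:
        s.network_id = renum[node_net[s.nodes[0]]]


def _node_segment_degree(graph: VesselGraph) -> dict:
    d: dict = {nid: 0 for nid in graph.nodes}
    for s in graph.segments:
        d[s.nodes[0]] += 1
        d[s.nodes[1]] += 1
    return d


def skeletonize_and_graph(
    cd31_mask: np.ndarray,
    spacing,
    prune_length: float | None = None,
    config: PipelineConfig | None = None,
) -> VesselGraph:
    """Thin the vessel mask and extract the segment graph.

    Spur segments (tip segments hanging off a junction) shorter than
    ``prune_length`` µm (default 5) are removed from the skeleton, which is
    then re-collapsed so adjacent segments merge.  An empty mask yields an
    empty graph.
    """
    if prune_length is None:
        prune_length = (config or PipelineConfig()).spur_prune_length
    spacing = np.asarray(spacing, dtype=float)
    mask = np.asarray(cd31_mask, dtype=bool)
    if not mask.any():
        return VesselGraph(spacing=tuple(spacing), shape=mask.shape)
    skel = skeletonize(mask).astype(bool)
    if not skel.any():
        # the 3D thinning of perfectly mirror-symmetric even-width tubes can
        # collapse to nothing; break the tie by shaving one voxel plane off
        # one side (half-voxel geometric bias, logged)
        import logging

        logging.getLogger(__name__).warning(
            "empty skeleton from non-empty mask; retrying with one-voxel shave"
        )
        for axes in ((0,), (1,), (0, 1)):
            shaved = mask
            for a in axes:
                shaved = shaved & np.roll(shaved, 1, axis=a)
            skel = skeletonize(shaved).astype(bool)
            if skel.any():
                break
    graph = _extract_graph(skel, spacing)
    for _ in range(10):
        if prune_length <= 0:
            break
        segdeg = _node_segment_degree(graph)
        spurs = [
            s
            for s in graph.segments
            if s.length < prune_length
            and s.nodes[0] != s.nodes[1]
            and (
                (segdeg[s.nodes[0]] == 1 and segdeg[s.nodes[1]] > 1)
                or (segdeg[s.nodes[1]] == 1 and segdeg[s.nodes[0]] > 1)
            )
        ]
        if not spurs:
            break
        for s in spurs:
            tip = s.nodes[0] if segdeg[s.nodes[0]] == 1 else s.nodes[1]
            junction = s.nodes[1] if tip == s.nodes[0] else s.nodes[0]
            junction_voxels = {tuple(v) for v in graph.nodes[junction]["voxels"]}
            for vox in s.path_voxels:
                if tuple(vox) not in junction_voxels:
                    skel[tuple(vox)] = False
            for vox in graph.nodes[tip]["voxels"]:
                skel[tuple(vox)] = False
        graph = _extract_graph(skel, spacing)
    return graph


def segment_diameters(
    graph: VesselGraph, cd31_mask: np.ndarray, spacing=None
) -> VesselGraph:
    """Fill per-segment mean diameters from the anisotropic EDT.

    The local radius at each skeleton point is its Euclidean distance (µm)
    to the nearest background voxel centre; a segment's mean diameter is
    twice the mean of its point radii.
    """
    spacing = np.asarray(spacing if spacing is not None else graph.spacing, dtype=float)
    if not graph.segments:
        return graph
    edt = ndimage.distance_transform_edt(np.asarray(cd31_mask, bool), sampling=spacing)
    for s in graph.segments:
        radii = edt[tuple(s.path_voxels.T)]
        if np.any(radii <= 0):
            raise TracingError(f"segment {s.id}: skeleton point outside the mask")
        s.mean_diameter = float(2.0 * radii.mean())
    return graph


def branch_levels(graph: VesselGraph) -> VesselGraph:
    """Assign each segment its hierarchical distance from the main branch.

    Per network, the main branch is the endpoint-to-endpoint simple path of
    maximal total length on a maximum-length spanning tree (tie-break:
    lexicographically smallest endpoint-id pair); its segments get level 0,
    every other tree segment level 1 + the level of the segment it attaches
    to, and cycle-closing chord segments 1 + min of the levels at their two
    attachment nodes.
    """
    seg_by_id = {s.id: s for s in graph.segments}
    for net in graph.network_ids:
        mg = graph.multigraph(net)
        mg.remove_nodes_from([n for n in mg.nodes if mg.degree(n) == 0])
        # split parallel edges / self-loops into tree candidates and chords
        best: dict = {}
        chords: list = []
        for u, v, k, data in mg.edges(keys=True, data=True):
            if u == v:
                chords.append((u, v, data["sid"]))
                continue
            key = (min(u, v), max(u, v))
            if key not in best or data["length"] > best[key][1]:
                if key in best:
                    chords.append((u, v, best[key][0]))
                best[key] = (data["sid"], data["length"])
            else:
                chords.append((u, v, data["sid"]))
        simple = nx.Graph()
        simple.add_nodes_from(mg.nodes)
        for (u, v), (sid, length) in best.items():
            simple.add_edge(u, v, sid=sid, length=length)
        tree = nx.maximum_spanning_tree(simple, weight="length")
        chords.extend(
            (u, v, data["sid"])
            for u, v, data in simple.edges(data=True)
            if not tree.has_edge(u, v)
        )

        # main branch: longest leaf-to-leaf path on the tree
        leaves = sorted(n for n in tree.nodes if tree.degree(n) <= 1)
        main_nodes: set = set(tree.nodes)  # single-node fallback
        main_sids: set = set()
        if len(leaves) >= 2:
            best_len, best_pair, best_path = -1.0, None, None
            for i, a in enumerate(leaves):
                dist, paths = nx.single_source_dijkstra(tree, a, weight="length")
                for b in leaves[i + 1 :]:
                    if b not in dist:
                        continue
                    pair = (a, b)
                    if dist[b] > best_len + 1e-12 or (
                        abs(dist[b] - best_len) <= 1e-12 and pair < best_pair
                    ):
                        best_len, best_pair, best_path = dist[b], pair, paths[b]
            main_nodes = set(best_path)
            main_sids = {
                tree.edges[u, v]["sid"] for u, v in zip(best_path, best_path[1:])
            }

        node_level = {n: 0 for n in main_nodes}
        for sid in main_sids:
            seg_by_id[sid].branch_level = 0
        # BFS outward from the main path over the tree
        frontier = sorted(main_nodes)
        seen = set(main_nodes)
        while frontier:
            nxt: list = []
            for n in frontier:
                for m in tree.neighbors(n):
                    if m in seen:
                        continue
                    sid = tree.edges[n, m]["sid"]
                    level = node_level[n] + 1
                    seg_by_id[sid].branch_level = level
                    node_level[m] = level
                    seen.add(m)
                    nxt.append(m)
            frontier = sorted(nxt)
        for u, v, sid in chords:
            seg_by_id[sid].branch_level = 1 + min(
                node_level.get(u, 0), node_level.get(v, 0)
            )
        # self-loop-only networks: the loop is its own main branch
        for s in graph.segments_of(net):
            if s.branch_level is None:
                s.branch_level = 0
            if s.nodes[0] == s.nodes[1] and len(graph.segments_of(net)) == 1:
                s.branch_level = 0
    return graph


def network_stats(graph: VesselGraph, cd31_mask: np.ndarray) -> pd.DataFrame:
    """Per-network totals and whole-VTS aggregates.

    Mask voxels are assigned to the network of the nearest skeleton voxel,
    partitioning the CD31 volume exactly.  The frame's ``attrs`` carry the
    aggregates: total PV length (µm), total CD31 volume (µm³), number of
    networks/segments, and the segments-per-network mean (the S/N statistic).
    """
    spacing = np.asarray(graph.spacing, dtype=float)
    voxel_vol = float(np.prod(spacing))
    mask = np.asarray(cd31_mask, bool)
    cols = ["network", "volume_um3", "length_um", "n_segments"]
    if not graph.segments:
        df = pd.DataFrame(columns=cols)
        df.attrs.update(
            total_length_um=0.0,
            total_volume_um3=float(mask.sum()) * voxel_vol,
            n_networks=0,
            n_segments=0,
            segments_per_network=np.nan,
        )
        return df
    label = np.zeros(graph.shape, dtype=np.int32)
    for s in graph.segments:
        label[tuple(s.path_voxels.T)] = s.network_id + 1
    _, (iz, iy, ix) = ndimage.distance_transform_edt(
        label == 0, sampling=spacing, return_indices=True
    )
    assigned = label[iz, iy, ix]
    rows = []
    for net in graph.network_ids:
        segs = graph.segments_of(net)
        vol = float(np.count_nonzero(mask & (assigned == net + 1))) * voxel_vol
        rows.append(
            {
                "network": net,
                "volume_um3": vol,
                "length_um": float(sum(s.length for s in segs)),
                "n_segments": len(segs),
            }
        )
    df = pd.DataFrame(rows, columns=cols)
    df.attrs.update(
        total_length_um=float(df["length_um"].sum()),
        total_volume_um3=float(mask.sum()) * voxel_vol,
        n_networks=len(df),
        n_segments=int(df["n_segments"].sum()),
        segments_per_network=float(df["n_segments"].mean()),
    )
    return df


def trace_vessels(
    cd31_mask: np.ndarray, spacing, config: PipelineConfig | None = None
) -> tuple[VesselGraph, pd.DataFrame]:
    """Full tracing pipeline: skeletonize, prune, diameters, branch levels, stats."""
    graph = skeletonize_and_graph(cd31_mask, spacing, config=config)
    if graph.segments:
        segment_diameters(graph, cd31_mask)
        branch_levels(graph)
    stats = network_stats(graph, cd31_mask)
    return graph, stats
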