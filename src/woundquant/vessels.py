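"""Vessel network analysis: segmentation cleanup, skeleton graph, sprouts.

The input is a pixel-probability map from an external vessel classifier
(values in [0, 1]) or, as a classical fallback, a binarized fluorescence
channel from the detection module. The chain: binarize at a probability
cutoff → morphological optimization (closing + hole filling) → fragment
filter (components larger than a physical volume) → skeletonization →
graph extraction (junction and end nodes, branch edges with geodesic
lengths in µm) → sprout classification.

A *sprout* is a terminal branch (single connection to the skeleton) that
does not result from clipping of the vessel at the image edge and is
shorter than a user cutoff — a proxy for new angiogenic growth. A *node*
is a junction where >= 3 branches meet; adjacent junction voxels are
merged into one node so counts do not depend on voxel parity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .stack import LabeledObjects, _as_voxel_size


def binarize_probability(prob_map: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Foreground = probability >= cutoff; values must lie in [0, 1]."""
    prob = np.asarray(prob_map, dtype=float)
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("probability map values must lie in [0, 1]")
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    return prob >= cutoff


def optimize_binary(binary: np.ndarray, n_iter: int = 1) -> np.ndarray:
    """Close gaps and fill holes: dilate × n, erode × n, fill holes.

    Idempotent on already-solid tubes; an empty image stays empty.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    binary = np.asarray(binary, dtype=bool)
    if n_iter:
        struct = ndimage.generate_binary_structure(binary.ndim, 1)
        binary = ndimage.binary_dilation(binary, structure=struct, iterations=n_iter)
        binary = ndimage.binary_erosion(binary, structure=struct, iterations=n_iter)
    return ndimage.binary_fill_holes(binary)


def filter_fragments(
    binary: np.ndarray, voxel_size, min_volume_um3: float = 100.0
) -> LabeledObjects:
    """Label connected fragments, keeping those strictly larger than
    ``min_volume_um3`` (default 100 µm³)."""
    binary = np.asarray(binary, dtype=bool)
    labels, _ = ndimage.label(binary, structure=np.ones((3,) * binary.ndim, dtype=bool))
    objects = LabeledObjects.from_labels(labels, voxel_size)
    keep = objects.table.loc[
        objects.table["volume_um3"] > min_volume_um3, "object_id"
    ].to_numpy()
    mask = np.isin(objects.labels, keep)
    return LabeledObjects.from_labels(np.where(mask, objects.labels, 0), voxel_size)


@dataclass
class VesselGraph:
    """Skeleton graph of a vessel network.

    Nodes carry ``kind`` ('junction', 'end' or 'isolated'), a pixel-space
    ``coord_px`` and a physical ``coord_um``. Edges (a MultiGraph — two
    junctions may be joined by parallel branches) carry ``length_um``, the
    voxel ``path``, and the ``terminal`` / ``clipped`` / ``sprout`` flags.
    """

    graph: nx.MultiGraph
    image_shape: tuple[int, ...]
    voxel_size: tuple[float, ...]
    vessel_volume_um3: float = 0.0
    sprout_length_cutoff_um: float | None = field(default=None)

    @property
    def total_length_um(self) -> float:
        return float(
            sum(d["length_um"] for _, _, d in self.graph.edges(data=True))
        )

    @property
    def n_junctions(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if d["kind"] == "junction")

    @property
    def n_end_points(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if d["kind"] == "end")

    @property
    def n_junction_voxels(self) -> int:
        return sum(
            d.get("n_voxels", 1)
            for _, d in self.graph.nodes(data=True)
            if d["kind"] == "junction"
        )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_sprouts(self) -> int:
        return sum(1 for _, _, d in self.graph.edges(data=True) if d.get("sprout"))

    def summary(self) -> dict:
        return {
            "vessel_volume_um3": self.vessel_volume_um3,
            "total_length_um": self.total_length_um,
            "n_edges": self.n_edges,
            "n_sprouts": self.n_sprouts,
            # junction definitions differ between tools; all three counts
            # are reported, merged junction clusters being canonical
            "n_nodes": self.n_junctions,
            "n_junction_voxels": self.n_junction_voxels,
            "n_nodes_incl_ends": self.n_junctions + self.n_end_points,
            "n_end_points": self.n_end_points,
        }


_NEIGHBOR_OFFSETS = {
    2: [
        (dy, dx)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dy, dx) != (0, 0)
    ],
    3: [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
}


def _skeleton_adjacency(coords: np.ndarray) -> list[list[int]]:
    """Neighbor lists for skeleton voxels under full connectivity."""
    index = {tuple(c): i for i, c in enumerate(coords)}
    offsets = _NEIGHBOR_OFFSETS[coords.shape[1]]
    neighbors: list[list[int]] = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in offsets:
            j = index.get(tuple(c + np.array(off)))
            if j is not None:
                neighbors[i].append(j)
    return neighbors


def _step_length(a, b, spacing) -> float:
    return float(np.sqrt(np.sum(((a - b) * spacing) ** 2)))


def _path_length(path: np.ndarray, spacing: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    return float(np.sqrt(np.sum((np.diff(path, axis=0) * spacing) ** 2, axis=1)).sum())


def skeleton_graph(objects: LabeledObjects) -> VesselGraph:
    """Skeletonize the vessel mask and extract its branch graph.

    Junction voxels (>= 3 skeleton neighbors) are merged into junction
    nodes when adjacent; end voxels (1 neighbor) become end nodes.
    Branches are chains of 2-neighbor voxels between nodes, with geodesic
    length summed over physical voxel steps. Single-voxel spurs hanging
    directly off a junction cluster are pruned as digitization artifacts.
    A blob with no branching yields a graph with 0 junctions.
    """
    mask = objects.labels > 0
    vs = _as_voxel_size(objects.voxel_size)
    spacing = np.array(vs[-mask.ndim :], dtype=float)
    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    graph = nx.MultiGraph()
    result = VesselGraph(
        graph=graph,
        image_shape=mask.shape,
        voxel_size=vs,
        vessel_volume_um3=objects.total_volume_um3,
    )
    if len(coords) == 0:
        return result

    neighbors = _skeleton_adjacency(coords)
    degree = np.array([len(n) for n in neighbors])

    # prune 1-voxel spurs: end voxels whose sole neighbor is a junction
    spurs = [
        i
        for i in range(len(coords))
        if degree[i] == 1 and degree[neighbors[i][0]] >= 3
    ]
    if spurs:
        keep = np.ones(len(coords), dtype=bool)
        keep[spurs] = False
        coords = coords[keep]
        neighbors = _skeleton_adjacency(coords)
        degree = np.array([len(n) for n in neighbors])

    n_vox = len(coords)
    is_node_voxel = degree != 2

    # merge adjacent junction voxels into one node; ends/isolated are solo
    node_of_voxel = np.full(n_vox, -1, dtype=int)
    next_node = 0
    junction_ids = np.where(degree >= 3)[0]
    seen = set()
    for start in junction_ids:
        if start in seen:
            continue
        cluster = [start]
        seen.add(int(start))
        stack = [int(start)]
        while stack:
            v = stack.pop()
            for w in neighbors[v]:
                if degree[w] >= 3 and w not in seen:
                    seen.add(int(w))
                    cluster.append(int(w))
                    stack.append(int(w))
        c_px = coords[cluster].mean(axis=0)
        graph.add_node(
            next_node,
            kind="junction",
            coord_px=tuple(c_px),
            coord_um=tuple(c_px * spacing),
            n_voxels=len(cluster),
        )
        node_of_voxel[cluster] = next_node
        next_node += 1
    for i in np.where((degree == 1) | (degree == 0))[0]:
        kind = "end" if degree[i] == 1 else "isolated"
        graph.add_node(
            next_node,
            kind=kind,
            coord_px=tuple(coords[i].astype(float)),
            coord_um=tuple(coords[i] * spacing),
            n_voxels=1,
        )
        node_of_voxel[i] = next_node
        next_node += 1

    # trace branches: walk degree-2 chains between node voxels
    visited_chain = np.zeros(n_vox, dtype=bool)
    direct_edges = set()  # dedupe node-voxel pairs directly adjacent

    def add_edge(a_vox: int, b_vox: int, path_idx: list[int]):
        na, nb = node_of_voxel[a_vox], node_of_voxel[b_vox]
        path = coords[path_idx]
        graph.add_edge(
            na,
            nb,
            length_um=_path_length(path, spacing),
            path=path,
            terminal=False,
            clipped=False,
            sprout=False,
        )

    for v in np.where(is_node_voxel)[0]:
        for w in neighbors[v]:
            if is_node_voxel[w]:
                if node_of_voxel[w] == node_of_voxel[v]:
                    continue  # internal to one junction cluster
                key = (min(v, w), max(v, w))
                if key in direct_edges:
                    continue
                direct_edges.add(key)
                add_edge(v, w, [v, w])
            else:
                if visited_chain[w]:
                    continue
                path_idx = [int(v), int(w)]
                prev, cur = int(v), int(w)
                while not is_node_voxel[cur]:
                    visited_chain[cur] = True
                    nxt = [u for u in neighbors[cur] if u != prev]
                    if not nxt:
                        break  # dead-end degree-2 anomaly
                    prev, cur = cur, int(nxt[0])
                    path_idx.append(cur)
                add_edge(path_idx[0], path_idx[-1], path_idx)

    # pure cycles (all degree-2): one synthetic node with a self-loop
    for s in range(n_vox):
        if degree[s] == 2 and not visited_chain[s] and node_of_voxel[s] == -1:
            path_idx = [s]
            visited_chain[s] = True
            prev, cur = s, neighbors[s][0]
            while cur != s:
                visited_chain[cur] = True
                path_idx.append(int(cur))
                nxt = [u for u in neighbors[cur] if u != prev]
                prev, cur = int(cur), int(nxt[0])
            path_idx.append(s)
            graph.add_node(
                next_node,
                kind="junction",
                coord_px=tuple(coords[s].astype(float)),
                coord_um=tuple(coords[s] * spacing),
                n_voxels=1,
            )
            node_of_voxel[s] = next_node
            path = coords[path_idx]
            graph.add_edge(
                next_node,
                next_node,
                length_um=_path_length(path, spacing),
                path=path,
                terminal=False,
                clipped=False,
                sprout=False,
            )
            next_node += 1
    return result


def _near_border(coord_px, shape, margin: int) -> bool:
    return any(
        c < margin or c > s - 1 - margin for c, s in zip(coord_px, shape)
    )


def classify_sprouts(
    vessel_graph: VesselGraph,
    max_sprout_length_um: float,
    border_margin_px: int = 2,
) -> VesselGraph:
    """Flag sprout edges in place and return the graph.

    An edge is a sprout iff it (1) has a single connection to the
    skeleton (one endpoint is an end node), (2) does not result from
    clipping at the image edge (its free end lies farther than
    ``border_margin_px`` from every image face) and (3) is shorter than
    ``max_sprout_length_um``.
    """
    if max_sprout_length_um <= 0:
        raise ValueError("max_sprout_length_um must be > 0")
    if border_margin_px < 0:
        raise ValueError("border_margin_px must be >= 0")
    g = vessel_graph.graph
    for a, b, key, d in g.edges(keys=True, data=True):
        kinds = (g.nodes[a]["kind"], g.nodes[b]["kind"])
        free_ends = [n for n in (a, b) if g.nodes[n]["kind"] == "end"]
        d["terminal"] = len(free_ends) >= 1 and "isolated" not in kinds
        d["clipped"] = any(
            _near_border(g.nodes[n]["coord_px"], vessel_graph.image_shape, border_margin_px)
            for n in free_ends
        )
        d["sprout"] = (
            d["terminal"]
            and not d["clipped"]
            and d["length_um"] < max_sprout_length_um
        )
    vessel_graph.sprout_length_cutoff_um = max_sprout_length_um
    return vessel_graph


def edge_table(vessel_graph: VesselGraph):
    """Edge list as records for CSV export."""
    rows = []
    for eid, (a, b, d) in enumerate(vessel_graph.graph.edges(data=True)):
        rows.append(
            {
                "edge_id": eid,
                "node_a": a,
                "node_b": b,
                "length_um": d["length_um"],
                "terminal": bool(d.get("terminal", False)),
                "clipped": bool(d.get("clipped", False)),
                "sprout": bool(d.get("sprout", False)),
            }
        )
    return rows
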