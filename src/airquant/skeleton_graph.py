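"""Centreline skeleton extraction and conversion to a rooted airway graph.

Pipeline: locate a trachea seed in the most superior slab of the mask,
thin the mask to a one-voxel centreline (topology-preserving 3D thinning),
break any residual cycles against a shortest-path spanning tree, then
collapse degree-2 chains into edges of a rooted acyclic graph whose nodes
are branch points and endpoints.

Voxel tie-breaking is everywhere by lowest flat index so identical inputs
produce identical graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from ._thinning import thin_3d
from .core_io import BinaryMask

__all__ = [
    "Skeleton",
    "AirwaySegment",
    "AirwayGraph",
    "find_trachea_seed",
    "skeletonize",
    "break_cycles",
    "skeleton_to_graph",
    "build_airway_graph",
]

log = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

# 26-neighbourhood offsets, fixed order for determinism.
_OFFSETS = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) != (0, 0, 0)],
    dtype=np.int64,
)


@dataclass
class Skeleton:
    """One-voxel-thick centreline of an airway mask.

    ``voxels`` is an (n, 3) int array of 0-based indices forming a single
    26-connected component that contains ``root_voxel`` (a voxel in the
    trachea). ``spacing``/``origin`` carry the world geometry of the grid.
    """

    voxels: np.ndarray
    root_voxel: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    shape: tuple[int, int, int]
    n_cycles_broken: int = 0

    def __len__(self) -> int:
        return len(self.voxels)

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out[tuple(self.voxels.T)] = True
        return out


@dataclass
class AirwaySegment:
    """One edge of the airway graph: an airway branch between two nodes.

    ``path_voxels`` runs proximal (parent node) to distal (child node) and
    consecutive voxels are 26-neighbours. Anatomy (lobe, generation) and
    measurements (spline, lengths, diameters) are filled by later stages.
    """

    id: int
    path_voxels: np.ndarray  # (n, 3) int
    lobe: str | None = None
    lobe_flagged: bool = False
    generation: int | None = None
    lobar_generation: int | None = None
    spline: object | None = None
    measurement: object | None = None

    @property
    def mean_diameter_mm(self) -> float | None:
        m = self.measurement
        if m is None or not getattr(m, "valid", False):
            return None
        return m.mean_diameter_mm


@dataclass
class AirwayGraph:
    """Rooted acyclic airway tree.

    ``tree`` is a :class:`networkx.DiGraph` whose nodes are integer ids with
    a ``voxel`` attribute and whose edges carry an :class:`AirwaySegment`
    under the ``segment`` attribute, oriented away from ``root_node``.
    """

    tree: nx.DiGraph
    root_node: int
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    shape: tuple[int, int, int]
    n_spurs_pruned: int = 0
    n_short_merged: int = 0
    n_cycles_broken: int = 0

    def segments(self) -> list[AirwaySegment]:
        """All segments in deterministic (id) order."""
        segs = [d["segment"] for _, _, d in self.tree.edges(data=True)]
        return sorted(segs, key=lambda s: s.id)

    def segment_edge(self, seg_id: int) -> tuple[int, int]:
        for u, v, d in self.tree.edges(data=True):
            if d["segment"].id == seg_id:
                return u, v
        raise KeyError(seg_id)

    def parent_segment(self, seg_id: int) -> AirwaySegment | None:
        u, _ = self.segment_edge(seg_id)
        preds = list(self.tree.predecessors(u))
        if not preds:
            return None
        return self.tree.edges[preds[0], u]["segment"]

    def node_world(self, node: int) -> np.ndarray:
        vox = np.asarray(self.tree.nodes[node]["voxel"], dtype=float)
        return np.asarray(self.origin) + vox * np.asarray(self.spacing)

    def path_world(self, segment: AirwaySegment) -> np.ndarray:
        return np.asarray(self.origin) + segment.path_voxels.astype(float) * np.asarray(
            self.spacing
        )

    @property
    def n_segments(self) -> int:
        return self.tree.number_of_edges()


def find_trachea_seed(mask: BinaryMask, slab_fraction: float = 0.05) -> tuple[int, int, int]:
    """Locate a seed voxel in the trachea.

    Takes the most superior ``slab_fraction`` of axial slices that contain
    foreground (at least one slice), finds the largest 26-connected component
    in that slab, and returns its foreground voxel nearest the component
    centroid. In RAS+ order, superior = highest z index.
    """
    fg_z = np.unique(np.nonzero(mask.data)[2])
    if fg_z.size == 0:
        raise ValueError("mask contains no foreground voxels")
    n_slab = max(1, int(np.ceil(slab_fraction * fg_z.size)))
    slab_z = fg_z[-n_slab:]
    slab = np.zeros_like(mask.data, dtype=bool)
    slab[:, :, slab_z] = mask.data[:, :, slab_z] != 0
    if not slab.any():
        raise ValueError("no foreground voxels in the superior slab")
    labels, n = ndimage.label(slab, structure=_STRUCT_26)
    sizes = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    idx = np.argwhere(labels == keep)
    centroid = idx.mean(axis=0)
    d2 = ((idx - centroid) ** 2).sum(axis=1)
    best = np.flatnonzero(d2 == d2.min())
    # tie-break on lowest flat index
    flat = np.ravel_multi_index(idx[best].T, mask.shape)
    return tuple(int(v) for v in idx[best[np.argmin(flat)]])


def skeletonize(mask: BinaryMask, seed: tuple[int, int, int]) -> Skeleton:
    """Thin the mask to a one-voxel centreline containing the seed.

    Uses sequential distance-ordered homotopic thinning (topology
    preserving by construction), then keeps the 26-connected skeleton
    component containing (or nearest to) the seed; the root voxel is the
    skeleton voxel nearest the seed.
    """
    if mask.data[seed] == 0:
        raise ValueError(f"seed voxel {seed} is not inside the mask")
    sk = thin_3d(mask.data, spacing=mask.spacing)
    if not sk.any():
        raise ValueError("thinning produced an empty skeleton")
    vox = np.argwhere(sk)
    d2 = ((vox - np.asarray(seed)) ** 2 * np.square(mask.spacing)).sum(axis=1)
    root = tuple(int(v) for v in vox[int(np.argmin(d2))])
    labels, _ = ndimage.label(sk, structure=_STRUCT_26)
    comp = labels == labels[root]
    return Skeleton(
        voxels=np.argwhere(comp),
        root_voxel=root,
        spacing=mask.spacing,
        origin=mask.origin,
        shape=mask.shape,
    )


def _adjacency(voxels: np.ndarray, shape: tuple[int, int, int], spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """26-adjacency among skeleton voxels.

    Returns (rows, cols, weights) over voxel-list indices (rows < cols) and
    a flat-index -> list-index lookup.
    """
    flat = np.ravel_multi_index(voxels.T, shape)
    lookup = {int(f): i for i, f in enumerate(flat)}
    sp = np.asarray(spacing)
    rows, cols, wts = [], [], []
    for off in _OFFSETS:
        nb = voxels + off
        ok = np.all((nb >= 0) & (nb < np.asarray(shape)), axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, shape)
        src = np.flatnonzero(ok)
        w = float(np.linalg.norm(off * sp))
        for i, f in zip(src, nb_flat):
            j = lookup.get(int(f))
            if j is not None and i < j:
                rows.append(i)
                cols.append(j)
                wts.append(w)
    return np.asarray(rows), np.asarray(cols), np.asarray(wts), lookup


def break_cycles(skeleton: Skeleton) -> Skeleton:
    """Remove genuine loops from the skeleton's voxel adjacency.

    Builds a shortest-path spanning tree from the root (Dijkstra, Euclidean
    step weights). For every non-tree adjacency whose fundamental cycle has
    at least 4 voxels (shorter "cycles" are just redundant diagonal
    adjacencies of a 26-connected curve, not loops), the cycle's farthest
    chain voxel (adjacency degree 2) from the root is deleted; iterated to
    a fixed point. The count of removals is recorded on the output.
    """
    voxels = skeleton.voxels
    removed = 0
    while True:
        rows, cols, wts, lookup = _adjacency(voxels, skeleton.shape, skeleton.spacing)
        n = len(voxels)
        if len(rows) == n - 1:
            break
        degree = np.zeros(n, dtype=int)
        np.add.at(degree, rows, 1)
        np.add.at(degree, cols, 1)
        graph = coo_matrix((wts, (rows, cols)), shape=(n, n))
        graph = graph + graph.T
        root_idx = lookup[int(np.ravel_multi_index(skeleton.root_voxel, skeleton.shape))]
        dist, pred = dijkstra(graph, indices=root_idx, return_predecessors=True)
        tree_edges = {
            (min(i, int(p)), max(i, int(p)))
            for i, p in enumerate(pred)
            if p >= 0
        }
        to_delete: set[int] = set()
        for i, j in zip(rows, cols):
            i, j = int(i), int(j)
            if (i, j) in tree_edges:
                continue
            # fundamental cycle = root-paths of i and j up to their meeting
            cycle = _cycle_nodes(i, j, pred)
            if len(cycle) < 4:
                continue
            chain = [k for k in cycle if degree[k] == 2 and k != root_idx]
            if not chain:
                continue
            to_delete.add(max(chain, key=lambda k: (dist[k], k)))
        if not to_delete:
            break
        removed += len(to_delete)
        keep = np.ones(n, dtype=bool)
        keep[list(to_delete)] = False
        voxels = voxels[keep]
        # keep root's component only
        lab_dense = np.zeros(skeleton.shape, dtype=bool)
        lab_dense[tuple(voxels.T)] = True
        labels, _ = ndimage.label(lab_dense, structure=_STRUCT_26)
        voxels = np.argwhere(labels == labels[skeleton.root_voxel])
    if removed:
        log.info("break_cycles: removed %d voxel(s) to break cycles", removed)
    return Skeleton(
        voxels=voxels,
        root_voxel=skeleton.root_voxel,
        spacing=skeleton.spacing,
        origin=skeleton.origin,
        shape=skeleton.shape,
        n_cycles_broken=skeleton.n_cycles_broken + removed,
    )


def _cycle_nodes(i: int, j: int, pred: np.ndarray) -> list[int]:
    path_i, path_j = [i], [j]
    seen_i = {i}
    a = i
    while pred[a] >= 0:
        a = int(pred[a])
        path_i.append(a)
        seen_i.add(a)
    b = j
    while b not in seen_i and pred[b] >= 0:
        b = int(pred[b])
        path_j.append(b)
    # truncate path_i at the meeting node
    if b in seen_i:
        path_i = path_i[: path_i.index(b) + 1]
    return path_i + path_j


def _path_length_mm(path: np.ndarray, spacing) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.diff(path.astype(float), axis=0) * np.asarray(spacing)
    return float(np.linalg.norm(steps, axis=1).sum())


def skeleton_to_graph(
    skeleton: Skeleton,
    min_length_mm: float = 2.0,
    prune_spurs: bool = True,
) -> AirwayGraph:
    """Convert an acyclic skeleton into a rooted airway graph.

    Chains are extracted over the skeleton's shortest-path spanning tree
    from the root (which discards the redundant diagonal adjacencies of a
    26-connected curve deterministically): nodes are voxels with != 2 tree
    neighbours (plus the root); edges are the maximal degree-2 chains
    between them, oriented away from the root. Terminal spurs shorter than
    ``min_length_mm`` are pruned (thinning artefacts), then remaining short
    internal segments are merged into their parent junction; both counts
    are logged and recorded.
    """
    voxels = skeleton.voxels
    shape = skeleton.shape
    rows, cols, wts, lookup = _adjacency(voxels, shape, skeleton.spacing)
    flat = np.ravel_multi_index(voxels.T, shape)
    n = len(voxels)
    root_idx = lookup[int(np.ravel_multi_index(skeleton.root_voxel, shape))]
    graph_m = coo_matrix((wts, (rows, cols)), shape=(n, n))
    graph_m = graph_m + graph_m.T
    _, pred = dijkstra(graph_m, indices=root_idx, return_predecessors=True)
    if np.any((pred < 0) & (np.arange(n) != root_idx)):
        raise ValueError("skeleton is not connected to the root; rebuild the skeleton")

    nbrs: list[list[int]] = [[] for _ in range(n)]
    for i, p in enumerate(pred):
        if p >= 0:
            nbrs[i].append(int(p))
            nbrs[int(p)].append(i)
    for lst in nbrs:
        lst.sort(key=lambda j: int(flat[j]))
    degree = np.array([len(l) for l in nbrs])
    is_node = (degree != 2).copy()
    is_node[root_idx] = True

    # walk chains between nodes
    g = nx.Graph()
    node_ids = np.flatnonzero(is_node)
    for ni in node_ids:
        g.add_node(int(ni))
    visited_pairs: set[tuple[int, int]] = set()
    for ni in sorted(node_ids, key=lambda i: int(flat[i])):
        for first in nbrs[ni]:
            chain = [int(ni), first]
            prev, cur = int(ni), first
            while not is_node[cur]:
                nxts = [k for k in nbrs[cur] if k != prev]
                if not nxts:
                    break
                prev, cur = cur, nxts[0]
                chain.append(cur)
            a, b = chain[0], chain[-1]
            key = (min(a, b), max(a, b), min(chain[1], chain[-2]) if len(chain) > 2 else -1)
            if key in visited_pairs:
                continue
            visited_pairs.add(key)
            path = voxels[chain]
            if g.has_edge(a, b):
                # parallel chain between same nodes would be a cycle
                raise ValueError("parallel chains found; skeleton is not acyclic")
            if a == b:
                raise ValueError("self-loop chain found; skeleton is not acyclic")
            g.add_edge(a, b, path=path)

    # orient away from root
    tree = nx.DiGraph()
    for n in g.nodes:
        tree.add_node(n, voxel=tuple(int(v) for v in voxels[n]))
    for u, v in nx.bfs_edges(g, root_idx):
        path = g.edges[u, v]["path"]
        if not np.array_equal(path[0], voxels[u]):
            path = path[::-1]
        tree.add_edge(u, v, path=path)

    n_spurs = 0
    if prune_spurs:
        n_spurs = _prune_spurs(tree, skeleton.spacing, min_length_mm, root_idx)
    _dissolve_degree2(tree, root_idx)
    n_merged = _merge_short_internal(tree, skeleton.spacing, min_length_mm, root_idx)
    _dissolve_degree2(tree, root_idx)

    # assign deterministic segment ids in BFS order
    graph = nx.DiGraph()
    for n in tree.nodes:
        graph.add_node(n, voxel=tree.nodes[n]["voxel"])
    seg_id = 0
    for u, v in nx.bfs_edges(tree, root_idx):
        seg = AirwaySegment(id=seg_id, path_voxels=tree.edges[u, v]["path"])
        graph.add_edge(u, v, segment=seg)
        seg_id += 1
    graph.remove_nodes_from([n for n in list(graph.nodes) if graph.degree(n) == 0 and n != root_idx])

    if n_spurs:
        log.info("pruned %d short spur(s)", n_spurs)
    if n_merged:
        log.info("merged %d short internal segment(s) into their parents", n_merged)
    return AirwayGraph(
        tree=graph,
        root_node=root_idx,
        spacing=skeleton.spacing,
        origin=skeleton.origin,
        shape=shape,
        n_spurs_pruned=n_spurs,
        n_short_merged=n_merged,
        n_cycles_broken=skeleton.n_cycles_broken,
    )


def _prune_spurs(tree: nx.DiGraph, spacing, min_length_mm: float, root: int) -> int:
    """Iteratively remove terminal edges shorter than min_length_mm."""
    n_pruned = 0
    changed = True
    while changed:
        changed = False
        for u, v in list(tree.edges):
            if tree.out_degree(v) == 0 and v != root:
                length = _path_length_mm(tree.edges[u, v]["path"], spacing)
                # only prune if the parent node keeps other children (a true spur)
                if length < min_length_mm and tree.out_degree(u) > 1:
                    tree.remove_edge(u, v)
                    tree.remove_node(v)
                    n_pruned += 1
                    changed = True
    return n_pruned


def _dissolve_degree2(tree: nx.DiGraph, root: int) -> None:
    """Merge through nodes with exactly one parent and one child."""
    changed = True
    while changed:
        changed = False
        for n in list(tree.nodes):
            if n == root:
                continue
            if tree.in_degree(n) == 1 and tree.out_degree(n) == 1:
                (p,) = tree.predecessors(n)
                (c,) = tree.successors(n)
                path = np.vstack(
                    [tree.edges[p, n]["path"], tree.edges[n, c]["path"][1:]]
                )
                tree.remove_node(n)
                tree.add_edge(p, c, path=path)
                changed = True


def _merge_short_internal(tree: nx.DiGraph, spacing, min_length_mm: float, root: int) -> int:
    """Suppress short internal edges by contracting their distal node.

    A short edge between two nearby junctions (typically a trifurcation that
    thinning split into two close bifurcations) is removed: its children
    re-attach to the proximal junction, with the short path prepended to each
    child's path so geometry stays contiguous. The parent junction then sees
    all children at one division.
    """
    n_merged = 0
    changed = True
    while changed:
        changed = False
        for u, v in list(tree.edges):
            if not tree.has_edge(u, v):
                continue
            if tree.out_degree(v) == 0:
                continue  # terminal; handled by spur pruning
            if tree.in_degree(u) == 0 and tree.out_degree(u) == 1:
                continue  # sole root edge: keep the trachea intact
            short_path = tree.edges[u, v]["path"]
            if _path_length_mm(short_path, spacing) >= min_length_mm:
                continue
            children = list(tree.successors(v))
            tree.remove_edge(u, v)
            for c in children:
                cpath = tree.edges[v, c]["path"]
                tree.remove_edge(v, c)
                tree.add_edge(u, c, path=np.vstack([short_path, cpath[1:]]))
            tree.remove_node(v)
            n_merged += 1
            changed = True
    return n_merged


def build_airway_graph(
    mask: BinaryMask,
    min_length_mm: float = 2.0,
    seed: tuple[int, int, int] | None = None,
) -> AirwayGraph:
    """Full skeleton stage: seed -> thinning -> cycle break -> graph."""
    if seed is None:
        seed = find_trachea_seed(mask)
    sk = skeletonize(mask, seed)
    sk = break_cycles(sk)
    return skeleton_to_graph(sk, min_length_mm=min_length_mm)


def export_edges_csv(graph: AirwayGraph, path) -> None:
    """Per-edge CSV: segment id, endpoint nodes, path length, parent id."""
    import pandas as pd

    rows = []
    for u, v, d in graph.tree.edges(data=True):
        seg = d["segment"]
        parent = graph.parent_segment(seg.id)
        rows.append(
            {
                "segment_id": seg.id,
                "node_proximal": u,
                "node_distal": v,
                "path_length_mm": _path_length_mm(seg.path_voxels, graph.spacing),
                "parent_id": parent.id if parent is not None else -1,
                "lobe": seg.lobe,
                "generation": seg.generation,
            }
        )
    pd.DataFrame(sorted(rows, key=lambda r: r["segment_id"])).to_csv(path, index=False)


def export_graphml(graph: AirwayGraph, path) -> None:
    """GraphML export with primitive node/edge attributes."""
    g = nx.DiGraph()
    for n, d in graph.tree.nodes(data=True):
        g.add_node(n, x=int(d["voxel"][0]), y=int(d["voxel"][1]), z=int(d["voxel"][2]))
    for u, v, d in graph.tree.edges(data=True):
        seg = d["segment"]
        g.add_edge(
            u,
            v,
            segment_id=seg.id,
            lobe=seg.lobe or "",
            generation=-1 if seg.generation is None else int(seg.generation),
            mean_diameter_mm=float(seg.mean_diameter_mm or -1.0),
        )
    nx.write_graphml(g, str(path))
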