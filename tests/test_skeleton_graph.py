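import numpy as np
import pytest

import airquant as aq
from airquant.core_io import BinaryMask
from airquant.skeleton_graph import (
    Skeleton,
    break_cycles,
    find_trachea_seed,
    skeleton_to_graph,
    skeletonize,
)


def _skeleton_from_voxels(voxels, shape=(40, 40, 40), root=None):
    voxels = np.asarray(voxels, dtype=int)
    return Skeleton(
        voxels=voxels,
        root_voxel=tuple(voxels[0] if root is None else root),
        spacing=(1.0, 1.0, 1.0),
        origin=(0.0, 0.0, 0.0),
        shape=shape,
    )


# ------------------------------------------------------------------- seed
def test_trachea_seed_on_vertical_cylinder_near_axis(tube_case):
    mask = tube_case["mask"]
    seed = find_trachea_seed(mask)
    fg_z = np.unique(np.nonzero(mask.data)[2])
    assert seed[2] >= fg_z[-max(1, int(np.ceil(0.05 * fg_z.size)))]
    # compare against the analytic axis position in that slice
    branch = tube_case["spec"].branches[0]
    axis_world = branch.centreline(np.array([0.02]))[0]
    axis_idx = mask.world_to_index(axis_world)
    assert np.hypot(seed[0] - axis_idx[0], seed[1] - axis_idx[1]) <= 2.0


def test_trachea_seed_lands_in_trachea_not_branch(y_case):
    mask = y_case["mask"]
    seed = find_trachea_seed(mask)
    fg_z = np.unique(np.nonzero(mask.data)[2])
    n_slab = max(1, int(np.ceil(0.05 * fg_z.size)))
    assert seed[2] in fg_z[-n_slab:]


def test_trachea_seed_requires_foreground():
    with pytest.raises(ValueError):
        BinaryMask(data=np.zeros((5, 5, 5), np.uint8), spacing=(1, 1, 1))


# ------------------------------------------------------------- skeletonize
def test_cylinder_skeleton_tracks_axis_per_slice(tube_case):
    mask = tube_case["mask"]
    sk = skeletonize(mask, find_trachea_seed(mask))
    branch = tube_case["spec"].branches[0]
    z_world = mask.index_to_world(sk.voxels.astype(float))[:, 2]
    t = (branch.start[2] - z_world) / (branch.start[2] - branch.end[2])
    axis = branch.centreline(np.clip(t, 0, 1))
    axis_idx = mask.world_to_index(axis)
    dev = np.linalg.norm(sk.voxels[:, :2] - axis_idx[:, :2], axis=1)
    # ignore the cone tips at the tube ends
    interior = (t > 0.1) & (t < 0.9)
    assert dev[interior].max() <= 1.0 + 1e-6


def test_y_phantom_has_single_bifurcation_voxel(y_case):
    mask = y_case["mask"]
    sk = skeletonize(mask, find_trachea_seed(mask))
    sk = break_cycles(sk)
    dense = sk.to_dense()
    vox = sk.voxels
    n3 = []
    for v in vox:
        lo = np.maximum(v - 1, 0)
        hi = np.minimum(v + 2, dense.shape)
        nb = int(dense[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].sum()) - 1
        if nb >= 3:
            n3.append(v)
    # junction voxels cluster at the analytic carina
    carina_world = np.asarray(y_case["spec"].branches[0].end)
    carina_idx = mask.world_to_index(carina_world)
    assert len(n3) >= 1
    d = np.linalg.norm(np.asarray(n3) - carina_idx, axis=1)
    assert d.min() <= 3.0


def test_single_voxel_curve_is_thinning_fixed_point():
    data = np.zeros((12, 12, 12), np.uint8)
    pts = [(i + 1, 5, i + 1) for i in range(9)]
    for p in pts:
        data[p] = 1
    mask = BinaryMask(data=data, spacing=(1, 1, 1))
    sk = skeletonize(mask, pts[0])
    assert sorted(map(tuple, sk.voxels)) == sorted(pts)


def test_skeletonize_rejects_seed_outside_mask(tube_case):
    with pytest.raises(ValueError):
        skeletonize(tube_case["mask"], (0, 0, 0))


# ------------------------------------------------------------ break_cycles
def test_break_cycles_identity_on_acyclic():
    path = [(5, 5, z) for z in range(5, 25)]
    sk = _skeleton_from_voxels(path)
    out = break_cycles(sk)
    assert out.n_cycles_broken == 0
    assert len(out) == len(path)


def _diamond_loop(cx, y, cz, k):
    """Diagonal-step (diamond) voxel loop in the x-z plane: triangle-free
    under 26-adjacency, so |E| - |V| + 1 counts genuine cycles."""
    loop = []
    for i in range(k):
        loop += [
            (cx + i, y, cz + (k - i)),
            (cx + (k - i), y, cz - i),
            (cx - i, y, cz - (k - i)),
            (cx - (k - i), y, cz + i),
        ]
    return sorted(set(loop))


def _cycle_count(skeleton):
    from airquant.skeleton_graph import _adjacency

    rows, _, _, _ = _adjacency(skeleton.voxels, skeleton.shape, skeleton.spacing)
    return len(rows) - len(skeleton.voxels) + 1


def test_break_cycles_removes_single_loop():
    tail = [(5, 5, z) for z in range(2, 11)]
    loop = _diamond_loop(5, 5, 14, 4)  # bottom tip at (5, 5, 10)
    vox = sorted(set(map(tuple, tail + loop)))
    sk = _skeleton_from_voxels(np.array(vox), root=(5, 5, 2))
    assert _cycle_count(sk) == 1
    out = break_cycles(sk)
    assert out.n_cycles_broken == 1
    assert _cycle_count(out) == 0


def test_break_cycles_removes_two_independent_loops():
    tail = [(5, 5, z) for z in range(2, 11)]
    bridge = [(5, 5, z) for z in range(19, 22)]
    loops = _diamond_loop(5, 5, 14, 4) + _diamond_loop(5, 5, 26, 4)
    vox = sorted(set(map(tuple, tail + bridge + loops)))
    sk = _skeleton_from_voxels(np.array(vox), root=(5, 5, 2))
    assert _cycle_count(sk) == 2
    out = break_cycles(sk)
    assert out.n_cycles_broken == 2
    assert _cycle_count(out) == 0


# --------------------------------------------------------- skeleton_to_graph
def test_y_skeleton_gives_three_edges():
    trunk = [(10, 10, z) for z in range(20, 11, -1)]
    left = [(10 - i, 10, 12 - i) for i in range(1, 8)]
    right = [(10 + i, 10, 12 - i) for i in range(1, 8)]
    sk = _skeleton_from_voxels(np.array(trunk + left + right), root=(10, 10, 20))
    g = skeleton_to_graph(sk, min_length_mm=1.0)
    assert g.tree.number_of_nodes() == 4
    assert g.n_segments == 3


def test_straight_line_gives_one_edge():
    path = [(5, 5, z) for z in range(5, 25)]
    sk = _skeleton_from_voxels(np.array(path), root=(5, 5, 5))
    g = skeleton_to_graph(sk)
    assert g.tree.number_of_nodes() == 2
    assert g.n_segments == 1
    seg = g.segments()[0]
    assert len(seg.path_voxels) == len(path)


def _binary_tree_skeleton():
    """Two-generation symmetric binary tree (7 branches) as voxel chains."""
    vox = []
    trunk = [(20, 20, z) for z in range(36, 27, -1)]
    vox += trunk
    for s1 in (-1, 1):
        for i in range(1, 8):
            vox.append((20 + s1 * i, 20, 28 - i))
        for s2 in (-1, 1):
            for j in range(1, 7):
                vox.append((20 + s1 * 7 + s2 * j, 20 + j, 21 - j))
    return np.array(sorted(set(vox)))


def test_symmetric_binary_tree_has_seven_edges():
    sk = _skeleton_from_voxels(_binary_tree_skeleton(), root=(20, 20, 36))
    g = skeleton_to_graph(sk, min_length_mm=1.0)
    assert g.n_segments == 7
    internal = [n for n in g.tree.nodes if g.tree.out_degree(n) == 2]
    assert len(internal) == 3


# ------------------------------------------------------------- invariants
def test_graph_partitions_skeleton_voxels(y_case):
    graph = y_case["graph"]
    counted = set()
    for seg in graph.segments():
        for v in map(tuple, seg.path_voxels):
            counted.add(v)
    # every node voxel and every interior voxel appears in some edge path
    for n, d in graph.tree.nodes(data=True):
        assert d["voxel"] in counted


@pytest.mark.parametrize("case_fixture", ["y_case"])
def test_acyclicity_edges_nodes(case_fixture, request):
    graph = request.getfixturevalue(case_fixture)["graph"]
    assert graph.tree.number_of_edges() == graph.tree.number_of_nodes() - 1


def test_graph_build_is_deterministic(y_case):
    g1 = aq.build_airway_graph(y_case["mask"])
    g2 = aq.build_airway_graph(y_case["mask"])
    s1 = [(s.id, s.path_voxels.tolist()) for s in g1.segments()]
    s2 = [(s.id, s.path_voxels.tolist()) for s in g2.segments()]
    assert s1 == s2


def test_segment_paths_are_26_connected_and_proximal_first(y_case):
    graph = y_case["graph"]
    for seg in graph.segments():
        steps = np.abs(np.diff(seg.path_voxels, axis=0))
        assert steps.max() <= 1
        u, v = graph.segment_edge(seg.id)
        assert tuple(seg.path_voxels[0]) == graph.tree.nodes[u]["voxel"]
        assert tuple(seg.path_voxels[-1]) == graph.tree.nodes[v]["voxel"]
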