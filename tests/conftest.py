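"""Shared fixtures: small rasterized phantoms and synthetic graph builders.

Heavy phantom cases are session-scoped so that rasterization, thinning and
calipers run once per test session.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

import airquant as aq
from airquant.caliper import PerpendicularPatch, SegmentMeasurement, fit_spline
from airquant.skeleton_graph import AirwayGraph, AirwaySegment

HALF_MAX = np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------- phantoms
@pytest.fixture(scope="session")
def tube_case():
    """Straight vertical tube, r=3 mm, 50 mm long, 0.6/0.7 mm voxels."""
    spec = aq.single_tube_spec(radius_mm=3.0, length_mm=50.0, spacing=(0.6, 0.6, 0.7))
    volume, mask, truth = aq.rasterize(spec)
    return {"spec": spec, "volume": volume, "mask": mask, "truth": truth}


@pytest.fixture(scope="session")
def tube_graph(tube_case):
    return aq.build_airway_graph(tube_case["mask"])


@pytest.fixture(scope="session")
def y_case():
    """Minimal branching tree: trachea + two children."""
    spec = aq.y_tree_spec()
    volume, mask, truth = aq.rasterize(spec)
    graph = aq.build_airway_graph(mask)
    return {"spec": spec, "volume": volume, "mask": mask, "truth": truth, "graph": graph}


@pytest.fixture(scope="session")
def narrowing_tree():
    """Six-lobe tree with uniform 25% child narrowing, fully measured."""
    spec = aq.build_standard_tree(child_ratio=0.75, base_radius_mm=6.5)
    volume, mask, truth = aq.rasterize(spec)
    graph = aq.build_airway_graph(mask)
    aq.assign_generations(graph)
    aq.classify_lobes(graph)
    aq.measure_graph(volume, graph)
    return {"spec": spec, "volume": volume, "mask": mask, "truth": truth, "graph": graph}


@pytest.fixture(scope="session")
def equal_tree_summary():
    """Equal-diameter (bronchiectatic) control tree, measured and summarized."""
    spec = aq.build_standard_tree(child_ratio=1.0, base_radius_mm=2.0)
    volume, mask, truth = aq.rasterize(spec)
    graph = aq.build_airway_graph(mask)
    aq.assign_generations(graph)
    aq.classify_lobes(graph)
    aq.measure_graph(volume, graph)
    return aq.summarize_patient(graph)


# ------------------------------------------------------- synthetic graphs
def make_graph(edge_paths: dict[tuple[int, int], np.ndarray], root: int) -> AirwayGraph:
    """Build an AirwayGraph directly from {(u, v): path_voxels} (unit spacing)."""
    tree = nx.DiGraph()
    nodes = {u for u, _ in edge_paths} | {v for _, v in edge_paths}
    for n in nodes:
        for (u, v), path in edge_paths.items():
            if n == u:
                tree.add_node(n, voxel=tuple(int(x) for x in path[0]))
            elif n == v:
                tree.add_node(n, voxel=tuple(int(x) for x in path[-1]))
    for i, ((u, v), path) in enumerate(sorted(edge_paths.items())):
        tree.add_edge(u, v, segment=AirwaySegment(id=i, path_voxels=np.asarray(path)))
    return AirwayGraph(
        tree=tree, root_node=root, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
        shape=(64, 64, 64),
    )


def attach_measurement(graph: AirwayGraph, diameters: dict[int, float]) -> None:
    """Give each segment a straight spline and a stub valid measurement."""
    for seg in graph.segments():
        seg.spline = fit_spline(graph.path_world(seg), graph.spacing)
        d = diameters.get(seg.id)
        seg.measurement = SegmentMeasurement(
            fits=[],
            arc_positions_mm=np.array([]),
            interval_mm=0.5,
            valid=d is not None,
            mean_diameter_mm=np.nan if d is None else d,
        )


def straight_path(start, stop, n=None):
    """Integer voxel path along one axis between two points (inclusive)."""
    start, stop = np.asarray(start), np.asarray(stop)
    n = int(np.abs(stop - start).max()) + 1 if n is None else n
    return np.round(np.linspace(start, stop, n)).astype(int)


# ------------------------------------------------------- analytic patches
def analytic_patch(
    r_u: float = 3.0,
    r_v: float | None = None,
    sigma: float = 0.5,
    pitch: float = 0.3,
    lumen: float = -1000.0,
    wall: float = 0.0,
    background: float = -850.0,
    half_extent_mm: float = 20.0,
) -> PerpendicularPatch:
    """Noise-free cross-section with a Gaussian wall whose inner half-max
    lies exactly on the (elliptical) lumen boundary."""
    r_v = r_u if r_v is None else r_v
    half = int(half_extent_mm / pitch)
    n = 2 * half + 1
    yy, xx = np.mgrid[:n, :n]
    X = (xx - half) * pitch
    Y = (yy - half) * pitch
    theta = np.arctan2(Y, X)
    rad = np.hypot(X, Y)
    r_dir = (
        r_u * r_v
        / np.sqrt((r_v * np.cos(theta)) ** 2 + (r_u * np.sin(theta)) ** 2)
    )
    rho_c = r_dir + sigma * HALF_MAX
    bump = np.exp(-((rad - rho_c) ** 2) / (2.0 * sigma**2))
    inner = lumen + (wall - lumen) * bump
    outer = background + (wall - background) * bump
    img = np.where(rad <= rho_c, inner, outer).astype(np.float32)
    return PerpendicularPatch(
        image=img,
        pitch_mm=pitch,
        centre_index=(float(half), float(half)),
        centre_world=np.zeros(3),
        basis=(np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
        oob_fraction=0.0,
    )
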