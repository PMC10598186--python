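"""Lobe and generation labelling of airway segments.

Generations count divisions from the trachea: the trachea is generation 0,
the main bronchi 1, so the lobar bronchi sit near generation 2 and the
standard analysis window of generations 2-6 starts at the lobar bronchi.

Lobe assignment is direction-based. At the first division the children are
split into right and left main bronchi by the lateral (x) component of
their mean direction. On the right, the most superior-directed child of the
right main bronchus seeds the right upper lobe (RUL); the remaining child
(bronchus intermedius) defaults to the right lower lobe (RLL) with its most
anterior-directed child re-seeding the right middle lobe (RML). On the
left, the most superior-directed child of the left main bronchus seeds the
upper-lobe complex (LUL), within which the most inferior-anterior division
seeds the lingula, labelled LML by convention; the remaining child seeds
the left lower lobe (LLL). Every descendant inherits its seed's lobe; an
explicit per-node override map takes precedence.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .skeleton_graph import AirwayGraph, AirwaySegment

__all__ = [
    "LOBES",
    "TRACHEA_MAIN",
    "assign_generations",
    "classify_lobes",
    "select_analysis_window",
]

log = logging.getLogger(__name__)

TRACHEA_MAIN = "TRACHEA_MAIN"
#: The six lung lobes; the lingula is treated as the left middle lobe (LML).
LOBES = ("RUL", "RML", "RLL", "LUL", "LML", "LLL")


def assign_generations(graph: AirwayGraph, root_generation: int = 0) -> AirwayGraph:
    """Assign generation numbers: trachea = ``root_generation`` (default 0,
    so main bronchi = 1 and lobar bronchi sit near 2), +1 at every division."""
    tree = graph.tree
    for u, v, d in tree.edges(data=True):
        seg: AirwaySegment = d["segment"]
        seg.generation = None
    import networkx as nx

    for u, v in nx.bfs_edges(tree, graph.root_node):
        seg = tree.edges[u, v]["segment"]
        preds = list(tree.predecessors(u))
        if not preds:
            seg.generation = root_generation
        else:
            parent = tree.edges[preds[0], u]["segment"]
            seg.generation = parent.generation + 1
    return graph


def _edge_direction(graph: AirwayGraph, u: int, v: int) -> np.ndarray:
    """Unit chord direction of an edge in world mm (proximal -> distal)."""
    path = graph.path_world(graph.tree.edges[u, v]["segment"])
    d = path[-1] - path[0]
    n = np.linalg.norm(d)
    return d / n if n > 0 else np.array([0.0, 0.0, -1.0])


def _label_subtree(graph: AirwayGraph, u: int, v: int, lobe: str, labels: dict) -> None:
    import networkx as nx

    labels[(u, v)] = lobe
    for a, b in nx.bfs_edges(graph.tree, v):
        labels[(a, b)] = lobe


def classify_lobes(
    graph: AirwayGraph,
    overrides: dict[int, str] | None = None,
) -> AirwayGraph:
    """Assign a lobe label to every segment (see module docstring).

    ``overrides`` maps a node id to a lobe; the node's entire subtree takes
    that label, overriding the heuristic (deeper overrides win). If the first
    division cannot be found, all segments are labelled TRACHEA_MAIN with a
    warning.
    """
    import networkx as nx

    tree = graph.tree
    if any(d["segment"].generation is None for _, _, d in tree.edges(data=True)):
        raise ValueError("generations must be assigned before lobe classification")

    labels: dict[tuple[int, int], str] = {}

    # walk from root to the first division (carina)
    node = graph.root_node
    while True:
        children = sorted(tree.successors(node), key=lambda n: tree.edges[node, n]["segment"].id)
        if len(children) == 0:
            warnings.warn("no airway division found; labelling everything TRACHEA_MAIN")
            for u, v in tree.edges:
                labels[(u, v)] = TRACHEA_MAIN
            _apply(graph, labels, overrides)
            return graph
        if len(children) >= 2:
            carina = node
            break
        labels[(node, children[0])] = TRACHEA_MAIN
        node = children[0]

    kids = sorted(tree.successors(carina), key=lambda n: tree.edges[carina, n]["segment"].id)
    dirs = {n: _edge_direction(graph, carina, n) for n in kids}
    right_main = max(kids, key=lambda n: dirs[n][0])  # +x = patient right
    left_main = min(kids, key=lambda n: dirs[n][0])
    if right_main == left_main or dirs[right_main][0] <= dirs[left_main][0]:
        warnings.warn("could not separate main bronchi; labelling TRACHEA_MAIN")
        for u, v in tree.edges:
            labels.setdefault((u, v), TRACHEA_MAIN)
        _apply(graph, labels, overrides)
        return graph
    labels[(carina, right_main)] = TRACHEA_MAIN
    labels[(carina, left_main)] = TRACHEA_MAIN
    for extra in kids:
        if extra not in (right_main, left_main):
            side = "R" if dirs[extra][0] > 0 else "L"
            _label_subtree(graph, carina, extra, "RLL" if side == "R" else "LLL", labels)

    _classify_right(graph, right_main, labels)
    _classify_left(graph, left_main, labels)

    # any unlabelled segment inherits its nearest labelled ancestor, flagged
    for u, v in nx.bfs_edges(tree, graph.root_node):
        if (u, v) not in labels:
            preds = list(tree.predecessors(u))
            lobe = labels.get((preds[0], u), TRACHEA_MAIN) if preds else TRACHEA_MAIN
            labels[(u, v)] = lobe
            tree.edges[u, v]["segment"].lobe_flagged = True

    _apply(graph, labels, overrides)
    return graph


def _classify_right(graph: AirwayGraph, right_main: int, labels: dict) -> None:
    tree = graph.tree
    kids = sorted(tree.successors(right_main), key=lambda n: tree.edges[right_main, n]["segment"].id)
    if not kids:
        return
    dirs = {n: _edge_direction(graph, right_main, n) for n in kids}
    rul = max(kids, key=lambda n: dirs[n][2])  # most superior-directed
    _label_subtree(graph, right_main, rul, "RUL", labels)
    rest = [n for n in kids if n != rul]
    if not rest:
        return
    if len(rest) == 1:
        # bronchus intermedius: defaults to RLL, most anterior child seeds RML
        bi = rest[0]
        _label_subtree(graph, right_main, bi, "RLL", labels)
        bi_kids = sorted(tree.successors(bi), key=lambda n: tree.edges[bi, n]["segment"].id)
        if len(bi_kids) >= 2:
            bi_dirs = {n: _edge_direction(graph, bi, n) for n in bi_kids}
            rml = max(bi_kids, key=lambda n: bi_dirs[n][1])  # most anterior
            _label_subtree(graph, bi, rml, "RML", labels)
    else:
        # trifurcation at the right main bronchus
        rml = max(rest, key=lambda n: dirs[n][1])
        _label_subtree(graph, right_main, rml, "RML", labels)
        for n in rest:
            if n != rml:
                _label_subtree(graph, right_main, n, "RLL", labels)


def _classify_left(graph: AirwayGraph, left_main: int, labels: dict) -> None:
    """Mirror of the right-side rule: the lingula is read as a left middle
    lobe, seeded by the most anterior-directed child of the left lower stem,
    so that mirroring a volume swaps R and L labels exactly."""
    tree = graph.tree
    kids = sorted(tree.successors(left_main), key=lambda n: tree.edges[left_main, n]["segment"].id)
    if not kids:
        return
    dirs = {n: _edge_direction(graph, left_main, n) for n in kids}
    lul = max(kids, key=lambda n: dirs[n][2])  # most superior-directed
    _label_subtree(graph, left_main, lul, "LUL", labels)
    rest = [n for n in kids if n != lul]
    if not rest:
        return
    if len(rest) == 1:
        li = rest[0]
        _label_subtree(graph, left_main, li, "LLL", labels)
        li_kids = sorted(tree.successors(li), key=lambda n: tree.edges[li, n]["segment"].id)
        if len(li_kids) >= 2:
            li_dirs = {n: _edge_direction(graph, li, n) for n in li_kids}
            lml = max(li_kids, key=lambda n: li_dirs[n][1])  # most anterior
            _label_subtree(graph, li, lml, "LML", labels)
    else:
        lml = max(rest, key=lambda n: dirs[n][1])
        _label_subtree(graph, left_main, lml, "LML", labels)
        for n in rest:
            if n != lml:
                _label_subtree(graph, left_main, n, "LLL", labels)


def _apply(graph: AirwayGraph, labels: dict, overrides: dict[int, str] | None) -> None:
    import networkx as nx

    tree = graph.tree
    for (u, v), lobe in labels.items():
        tree.edges[u, v]["segment"].lobe = lobe
    if overrides:
        order = dict(nx.shortest_path_length(tree, graph.root_node))
        for node in sorted(overrides, key=lambda n: order.get(n, 10**9)):
            lobe = overrides[node]
            if node not in tree:
                warnings.warn(f"override node {node} not in graph; skipped")
                continue
            for child in tree.successors(node):
                lab: dict = {}
                _label_subtree(graph, node, child, lobe, lab)
                for (u, v), lb in lab.items():
                    tree.edges[u, v]["segment"].lobe = lb
                    tree.edges[u, v]["segment"].lobe_flagged = False
    _assign_lobar_generations(graph)


def _assign_lobar_generations(graph: AirwayGraph) -> None:
    """Generation counted from each lobe's seeding bronchus."""
    import networkx as nx

    tree = graph.tree
    for u, v in nx.bfs_edges(tree, graph.root_node):
        seg = tree.edges[u, v]["segment"]
        preds = list(tree.predecessors(u))
        if not preds:
            seg.lobar_generation = 0
            continue
        parent = tree.edges[preds[0], u]["segment"]
        if seg.lobe == parent.lobe:
            seg.lobar_generation = (parent.lobar_generation or 0) + 1
        else:
            seg.lobar_generation = 0


def select_analysis_window(
    graph: AirwayGraph, gen_lo: int = 2, gen_hi: int = 6
) -> dict[str, list[AirwaySegment]]:
    """Segments with gen_lo <= generation <= gen_hi, grouped by lobe."""
    if not (0 <= gen_lo <= gen_hi):
        raise ValueError(f"invalid generation window [{gen_lo}, {gen_hi}]")
    out: dict[str, list[AirwaySegment]] = {}
    for seg in graph.segments():
        if seg.generation is None:
            raise ValueError("generations must be assigned before windowing")
        if gen_lo <= seg.generation <= gen_hi:
            out.setdefault(seg.lobe or "UNLABELLED", []).append(seg)
    return out
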