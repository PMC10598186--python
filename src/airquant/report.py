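"""Pipeline orchestration, run configuration, and graph rendering.

``run_pipeline`` executes mask preparation -> skeleton/graph -> lobe and
generation labelling -> calipers -> biomarkers for one case, writing
``segments.csv``, ``patient_summary.csv``, ``graph.graphml``, a PNG airway
map, a run log with per-stage counts (voxels in, skeleton voxels, cycles
broken, spurs pruned, segments, valid measurements) and the resolved
config. Re-running from the saved config reproduces the CSVs byte for
byte: the pipeline itself has no randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import anatomy, caliper, core_io, mask_prep, metrics, skeleton_graph
from .caliper import CaliperConfig
from .skeleton_graph import AirwayGraph

__all__ = ["RunConfig", "run_pipeline", "render_airway_graph"]

log = logging.getLogger(__name__)

LOBE_COLOURS = {
    "RUL": "#d62728",
    "RML": "#ff7f0e",
    "RLL": "#bcbd22",
    "LUL": "#1f77b4",
    "LML": "#9467bd",
    "LLL": "#2ca02c",
    "TRACHEA_MAIN": "#7f7f7f",
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    ct_path: str
    airway_path: str
    out_dir: str
    patient_id: str = "case"
    close_radius_mm: float | None = None  # None: 1-voxel equivalent
    min_segment_length_mm: float = 2.0
    gen_lo: int = 2
    gen_hi: int = 6
    lobe_overrides_path: str | None = None
    caliper: CaliperConfig = field(default_factory=CaliperConfig)
    seed: int = 0
    log_level: str = "INFO"

    def save(self, path: str | Path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload["caliper"] = CaliperConfig(**payload.get("caliper", {}))
        return cls(**payload)


def _read_overrides(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path)
    if not {"node_id", "lobe"} <= set(df.columns):
        raise ValueError("overrides file needs columns node_id,lobe")
    return {int(r.node_id): str(r.lobe) for r in df.itertuples()}


def run_pipeline(config: RunConfig) -> Path:
    """Run the full quantification pipeline for one case.

    Returns the output directory; raises with the failing stage's name on
    any stage error. The output summary row carries a validity flag.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    counts: dict[str, float] = {}

    def stage(name):
        log.info("stage: %s", name)
        return name

    name = stage("load")
    try:
        volume = core_io.load_volume(config.ct_path)
        mask = core_io.load_mask(config.airway_path, volume)
        counts["mask_voxels_in"] = int(mask.data.sum())

        name = stage("mask_prep")
        mask = mask_prep.prepare_mask(mask, config.close_radius_mm)
        counts["mask_voxels_prepared"] = int(mask.data.sum())

        name = stage("skeleton_graph")
        seed = skeleton_graph.find_trachea_seed(mask)
        sk = skeleton_graph.skeletonize(mask, seed)
        counts["skeleton_voxels"] = len(sk)
        sk = skeleton_graph.break_cycles(sk)
        counts["cycles_broken"] = sk.n_cycles_broken
        graph = skeleton_graph.skeleton_to_graph(sk, config.min_segment_length_mm)
        counts["spurs_pruned"] = graph.n_spurs_pruned
        counts["short_segments_merged"] = graph.n_short_merged
        counts["segments"] = graph.n_segments

        name = stage("anatomy")
        anatomy.assign_generations(graph)
        overrides = (
            _read_overrides(config.lobe_overrides_path)
            if config.lobe_overrides_path
            else None
        )
        anatomy.classify_lobes(graph, overrides)

        name = stage("caliper")
        caliper.measure_graph(volume, graph, config.caliper)
        counts["segments_measured_valid"] = sum(
            1 for s in graph.segments() if s.measurement is not None and s.measurement.valid
        )

        name = stage("metrics")
        rows = metrics.compute_segment_metrics(graph)
        seg_df = metrics.segment_metrics_frame(rows)
        summary = metrics.summarize_patient(
            graph, config.patient_id, config.gen_lo, config.gen_hi
        )
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    seg_df.to_csv(out / "segments.csv", index=False, float_format="%.6f")
    pd.DataFrame([summary.to_row()]).to_csv(
        out / "patient_summary.csv", index=False, float_format="%.6f"
    )
    skeleton_graph.export_graphml(graph, out / "graph.graphml")
    skeleton_graph.export_edges_csv(graph, out / "edges.csv")
    caliper.export_samples_csv(graph, out / "samples.csv")
    render_airway_graph(graph, out / "airway_graph.png")
    config.save(out / "config.json")
    counts["summary_valid"] = bool(summary.valid)
    counts["tapering_sign_convention"] = metrics.TAPERING_SIGN_CONVENTION
    with open(out / "run_log.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    return out


def _tree_layout(graph: AirwayGraph) -> dict[int, tuple[float, float]]:
    """Simple hierarchical layout: leaves spread on x, depth on -y."""
    import networkx as nx

    tree = graph.tree
    depth = {graph.root_node: 0}
    for u, v in nx.bfs_edges(tree, graph.root_node):
        depth[v] = depth[u] + 1
    pos: dict[int, tuple[float, float]] = {}
    next_x = [0.0]

    def place(n: int) -> float:
        children = sorted(tree.successors(n), key=lambda c: tree.edges[n, c]["segment"].id)
        if not children:
            x = next_x[0]
            next_x[0] += 1.0
        else:
            x = float(np.mean([place(c) for c in children]))
        pos[n] = (x, -float(depth[n]))
        return x

    place(graph.root_node)
    return pos


def render_airway_graph(graph: AirwayGraph, path: str | Path) -> Path:
    """Draw the airway tree: edge width proportional to mean lumen
    diameter, edge colour by lobe, nodes at airway divisions."""
    import warnings

    pos = _tree_layout(graph)
    diameters = {
        d["segment"].id: d["segment"].mean_diameter_mm
        for _, _, d in graph.tree.edges(data=True)
    }
    known = [v for v in diameters.values() if v is not None and np.isfinite(v)]
    if not known:
        warnings.warn("no diameters available; drawing uniform edge widths")
    scale = 4.0 / max(known) if known else None

    fig, ax = plt.subplots(figsize=(8, 6))
    for u, v, d in graph.tree.edges(data=True):
        seg = d["segment"]
        dia = diameters[seg.id]
        lw = 1.5 if scale is None or dia is None or not np.isfinite(dia) else max(0.3, dia * scale)
        colour = LOBE_COLOURS.get(seg.lobe or "TRACHEA_MAIN", "#000000")
        (x0, y0), (x1, y1) = pos[u], pos[v]
        ax.plot([x0, x1], [y0, y1], color=colour, linewidth=lw, solid_capstyle="round")
    xs = [p[0] for p in pos.values()]
    ys = [p[1] for p in pos.values()]
    ax.scatter(xs, ys, s=6, color="k", zorder=3)
    ax.set_axis_off()
    ax.set_title("Airway graph (width ~ mean lumen diameter, colour = lobe)")
    handles = [
        plt.Line2D([0], [0], color=c, lw=3, label=l) for l, c in LOBE_COLOURS.items()
    ]
    ax.legend(handles=handles, fontsize=7, loc="lower right")
    fig.savefig(path, dpi=130, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
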