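"""Airway biomarkers: intersegmental tapering, segmental tortuosity, and
per-patient summaries over the generation 2-6 analysis window.

Intersegmental tapering of a child segment with mean diameter d and parent
mean diameter d_p is 100 * (d_p - d) / d_p: positive when the child is
narrower than its parent (normal distal narrowing), negative for a dilated
child. Reduced tapering is the traction-bronchiectasis signature. The sign
convention is recorded in the exported metadata.

Segmental tortuosity is L_a / L_e, the ratio of a segment's centreline arc
length to the straight distance between its endpoints; 1 for a straight
segment, larger when the airway is pulled into a curved course.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import LOBES, TRACHEA_MAIN
from .skeleton_graph import AirwayGraph, AirwaySegment

__all__ = [
    "TAPERING_SIGN_CONVENTION",
    "SegmentMetrics",
    "PatientSummary",
    "intersegmental_tapering",
    "tortuosity",
    "compute_segment_metrics",
    "summarize_patient",
    "export_survival_table",
]

TAPERING_SIGN_CONVENTION = (
    "tapering_pct = 100 * (parent_diameter - child_diameter) / parent_diameter; "
    "positive = child narrower than parent"
)


def intersegmental_tapering(d_p: float, d: float) -> float:
    """Percent diameter change from parent to child segment."""
    if d_p <= 0 or d <= 0:
        raise ValueError(f"diameters must be positive, got d_p={d_p}, d={d}")
    return 100.0 * (d_p - d) / d_p


def tortuosity(L_a: float, L_e: float, rel_tol: float = 1e-6) -> float:
    """Arc-length / Euclidean-length ratio of a segment (>= 1)."""
    if L_e <= 0:
        raise ValueError(f"Euclidean length must be positive, got {L_e}")
    ratio = L_a / L_e
    if ratio < 1.0 - rel_tol:
        raise ValueError(f"arc length {L_a} < Euclidean length {L_e}")
    return max(ratio, 1.0)


@dataclass
class SegmentMetrics:
    """Per-segment biomarker row."""

    segment_id: int
    lobe: str | None
    generation: int | None
    lobar_generation: int | None
    mean_diameter_mm: float
    parent_mean_diameter_mm: float
    intersegmental_tapering_pct: float
    tortuosity: float
    arc_length_mm: float
    euclidean_length_mm: float
    valid: bool


@dataclass
class PatientSummary:
    """Patient-level aggregate over the analysis window.

    Medians are taken over valid window segments only (midpoint convention
    for even counts); ``total_segment_count`` counts every identified
    segment in the tree, not just the window.
    """

    patient_id: str
    median_intersegmental_tapering_pct: float
    median_tortuosity: float
    total_segment_count: int
    n_window_segments: int
    n_valid_window_segments: int
    gen_lo: int
    gen_hi: int
    valid: bool
    per_lobe: dict[str, dict[str, float]] = field(default_factory=dict)
    per_generation: dict[int, dict[str, float]] = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "median_intersegmental_tapering_pct": self.median_intersegmental_tapering_pct,
            "median_tortuosity": self.median_tortuosity,
            "total_segment_count": self.total_segment_count,
            "n_window_segments": self.n_window_segments,
            "n_valid_window_segments": self.n_valid_window_segments,
            "gen_lo": self.gen_lo,
            "gen_hi": self.gen_hi,
            "valid": self.valid,
        }


def compute_segment_metrics(graph: AirwayGraph) -> list[SegmentMetrics]:
    """Biomarkers for every segment of a measured graph.

    The root (trachea) segment has no parent and contributes no tapering;
    a segment is a valid biomarker row when its own and its parent's
    diameter measurements are valid and its spline lengths are positive.
    """
    rows: list[SegmentMetrics] = []
    for seg in graph.segments():
        d = seg.mean_diameter_mm
        parent = graph.parent_segment(seg.id)
        d_p = parent.mean_diameter_mm if parent is not None else None
        if seg.spline is not None and seg.spline.euclidean_length_mm > 0:
            tort = tortuosity(seg.spline.arc_length_mm, seg.spline.euclidean_length_mm)
            la, le = seg.spline.arc_length_mm, seg.spline.euclidean_length_mm
        else:
            tort, la, le = np.nan, np.nan, np.nan
        if d is not None and d_p is not None and d > 0 and d_p > 0:
            taper = intersegmental_tapering(d_p, d)
        else:
            taper = np.nan
        rows.append(
            SegmentMetrics(
                segment_id=seg.id,
                lobe=seg.lobe,
                generation=seg.generation,
                lobar_generation=seg.lobar_generation,
                mean_diameter_mm=np.nan if d is None else d,
                parent_mean_diameter_mm=np.nan if d_p is None else d_p,
                intersegmental_tapering_pct=taper,
                tortuosity=tort,
                arc_length_mm=la,
                euclidean_length_mm=le,
                valid=bool(np.isfinite(tort) and d is not None),
            )
        )
    return rows


def segment_metrics_frame(rows: list[SegmentMetrics]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def _median(values: list[float]) -> float:
    vals = [v for v in values if np.isfinite(v)]
    return float(np.median(vals)) if vals else np.nan


def summarize_patient(
    graph: AirwayGraph,
    patient_id: str = "case",
    gen_lo: int = 2,
    gen_hi: int = 6,
) -> PatientSummary:
    """Median tapering and tortuosity across the generation window.

    Airways are analysed on a lobar basis: per-lobe (and per-generation)
    medians are included alongside the whole-window medians. A summary with
    zero valid window segments is flagged invalid.
    """
    rows = compute_segment_metrics(graph)
    window = [
        r
        for r in rows
        if r.generation is not None and gen_lo <= r.generation <= gen_hi
    ]
    valid_rows = [r for r in window if r.valid]

    per_lobe: dict[str, dict[str, float]] = {}
    for lobe in LOBES:
        sub = [r for r in valid_rows if r.lobe == lobe]
        if sub:
            per_lobe[lobe] = {
                "median_intersegmental_tapering_pct": _median(
                    [r.intersegmental_tapering_pct for r in sub]
                ),
                "median_tortuosity": _median([r.tortuosity for r in sub]),
                "n_segments": len(sub),
            }
    per_gen: dict[int, dict[str, float]] = {}
    for gen in range(gen_lo, gen_hi + 1):
        sub = [r for r in valid_rows if r.generation == gen]
        if sub:
            per_gen[gen] = {
                "median_intersegmental_tapering_pct": _median(
                    [r.intersegmental_tapering_pct for r in sub]
                ),
                "median_tortuosity": _median([r.tortuosity for r in sub]),
                "n_segments": len(sub),
            }

    return PatientSummary(
        patient_id=patient_id,
        median_intersegmental_tapering_pct=_median(
            [r.intersegmental_tapering_pct for r in valid_rows]
        ),
        median_tortuosity=_median([r.tortuosity for r in valid_rows]),
        total_segment_count=graph.n_segments,
        n_window_segments=len(window),
        n_valid_window_segments=len(valid_rows),
        gen_lo=gen_lo,
        gen_hi=gen_hi,
        valid=len(valid_rows) > 0,
        per_lobe=per_lobe,
        per_generation=per_gen,
    )


def export_survival_table(
    summaries: list[PatientSummary],
    clinical: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per patient, ready for survival modelling.

    Columns: patient id, median tapering, median tortuosity, total segment
    count; clinical covariates are joined on ``patient_id`` when provided.
    Duplicate patient ids raise.
    """
    ids = [s.patient_id for s in summaries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient id(s): {dupes}")
    table = pd.DataFrame(
        {
            "patient_id": ids,
            "median_intersegmental_tapering_pct": [
                s.median_intersegmental_tapering_pct for s in summaries
            ],
            "median_tortuosity": [s.median_tortuosity for s in summaries],
            "total_segment_count": [s.total_segment_count for s in summaries],
        }
    )
    if clinical is not None:
        if "patient_id" not in clinical.columns:
            raise ValueError("clinical table must have a patient_id column")
        table = table.merge(clinical, on="patient_id", how="left")
    table.attrs["tapering_sign_convention"] = TAPERING_SIGN_CONVENTION
    return table


def standardize_tortuosity(table: pd.DataFrame) -> pd.DataFrame:
    """Optional cohort z-standardization of the tortuosity column."""
    out = table.copy()
    col = out["median_tortuosity"]
    sd = col.std(ddof=1)
    out["median_tortuosity_z"] = (col - col.mean()) / sd if sd > 0 else np.nan
    return out
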