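"""Cap-and-sum aggregation of visually scored traction bronchiectasis.

Radiologists score traction bronchiectasis per lobe (six lobes, with the
lingula counted as a sixth lobe in place of a left middle lobe). Extent is
the number of involved airway segments per lobe, capped at 3 in the upper
and lower lobes and 2 in the middle lobes (maximum whole-lung score 16).
Severity is a 0-3 grade per lobe (maximum whole-lung score 18). The
scoring itself is a human judgement; this module only aggregates it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "LobeScoreSet",
    "EXTENT_CAPS",
    "SEVERITY_CAP",
    "aggregate_tb_extent",
    "aggregate_tb_severity",
    "aggregate_table",
]

SIX_LOBES = ("RUL", "RML", "RLL", "LUL", "LML", "LLL")

#: Per-lobe extent caps: 3 in upper/lower lobes, 2 in the middle lobes.
EXTENT_CAPS = {"RUL": 3, "RML": 2, "RLL": 3, "LUL": 3, "LML": 2, "LLL": 3}
#: Severity cap, identical for every lobe.
SEVERITY_CAP = 3


@dataclass
class LobeScoreSet:
    """Raw per-lobe scores of one kind ('extent' or 'severity')."""

    scores: dict[str, int]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("extent", "severity"):
            raise ValueError(f"kind must be 'extent' or 'severity', got {self.kind!r}")
        unknown = set(self.scores) - set(SIX_LOBES)
        if unknown:
            raise ValueError(f"unknown lobe(s): {sorted(unknown)}")
        for lobe, value in self.scores.items():
            if int(value) != value or value < 0:
                raise ValueError(f"score for {lobe} must be a non-negative integer, got {value}")


def aggregate_tb_extent(scores: LobeScoreSet) -> int:
    """Whole-lung extent score: cap each lobe, then sum (max 16)."""
    if scores.kind != "extent":
        raise ValueError(f"expected extent scores, got kind={scores.kind!r}")
    return sum(min(scores.scores.get(lobe, 0), cap) for lobe, cap in EXTENT_CAPS.items())


def aggregate_tb_severity(scores: LobeScoreSet) -> int:
    """Whole-lung severity score: cap each lobe at 3, then sum (max 18)."""
    if scores.kind != "severity":
        raise ValueError(f"expected severity scores, got kind={scores.kind!r}")
    return sum(min(scores.scores.get(lobe, 0), SEVERITY_CAP) for lobe in SIX_LOBES)


def aggregate_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a long-format score table to one row per patient.

    Input columns: ``patient_id, lobe, kind, value``. Output columns:
    ``patient_id, tb_extent, tb_severity`` (missing lobes count as 0).
    """
    required = {"patient_id", "lobe", "kind", "value"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    rows = []
    for pid, sub in raw.groupby("patient_id", sort=True):
        ext = sub[sub["kind"] == "extent"]
        sev = sub[sub["kind"] == "severity"]
        rows.append(
            {
                "patient_id": pid,
                "tb_extent": aggregate_tb_extent(
                    LobeScoreSet(dict(zip(ext["lobe"], ext["value"])), "extent")
                ),
                "tb_severity": aggregate_tb_severity(
                    LobeScoreSet(dict(zip(sev["lobe"], sev["value"])), "severity")
                ),
            }
        )
    return pd.DataFrame(rows)
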