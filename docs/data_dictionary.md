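# Output data dictionary

Sign convention for tapering throughout:
`tapering_pct = 100 * (parent_diameter - child_diameter) / parent_diameter`
— positive when the child is narrower than its parent (normal distal
narrowing); reduced values indicate traction bronchiectasis.

## segments.csv (one row per airway segment)

| column | units | meaning |
| --- | --- | --- |
| segment_id | – | deterministic id, breadth-first from the trachea |
| lobe | – | TRACHEA_MAIN, RUL, RML, RLL, LUL, LML (lingula), LLL |
| generation | – | divisions from the trachea (trachea = 0) |
| lobar_generation | – | divisions from the segment's lobar seed bronchus |
| mean_diameter_mm | mm | mean FWHM ellipse diameter over valid samples |
| parent_mean_diameter_mm | mm | same, for the parent segment (NaN at the root) |
| intersegmental_tapering_pct | % | see sign convention above (NaN at the root) |
| tortuosity | – | arc length / Euclidean length of the centreline (≥ 1) |
| arc_length_mm | mm | centreline spline arc length L_a |
| euclidean_length_mm | mm | straight distance between spline endpoints L_e |
| valid | – | True when diameter and lengths are both measurable |

## patient_summary.csv (one row per case)

| column | units | meaning |
| --- | --- | --- |
| patient_id | – | case identifier |
| median_intersegmental_tapering_pct | % | median over valid window segments |
| median_tortuosity | – | median over valid window segments |
| total_segment_count | – | all identified segments, whole tree |
| n_window_segments | – | segments with gen_lo ≤ generation ≤ gen_hi |
| n_valid_window_segments | – | of those, with valid measurements |
| gen_lo, gen_hi | – | analysis window used (default 2 and 6) |
| valid | – | False when no valid window segment exists |

## samples.csv (one row per caliper sample)

| column | units | meaning |
| --- | --- | --- |
| segment_id | – | owning segment |
| arc_position_mm | mm | position along the segment spline |
| diameter_mm | mm | geometric-mean ellipse diameter (NaN if invalid) |
| valid | – | ray/ellipse acceptance of this cross-section |
| n_rays_used | – | boundary rays surviving rejection and outlier removal |

## edges.csv (one row per graph edge)

segment_id, proximal/distal node ids, voxel path length (mm), parent
segment id (−1 at the root), lobe, generation.

## run_log.json

Per-stage counts for auditability: input/prepared mask voxels, skeleton
voxels, cycles broken, spurs pruned, short segments merged, segments,
valid measurements, summary validity, and the tapering sign convention.
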