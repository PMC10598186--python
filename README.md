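# airquant

Automated airway-tree quantification from chest CT, for researchers studying
airway remodelling in fibrosing lung disease (idiopathic pulmonary fibrosis
in particular). Given a CT volume and a binary airway-lumen segmentation,
the package derives a rooted acyclic airway graph, labels lobes and
generations, measures lumen diameters with perpendicular-plane FWHM ellipse
calipers, and summarizes two prognostic biomarkers per patient across airway
generations 2–6:

* **Intersegmental tapering** of a child segment with mean lumen diameter
  *d* and parent diameter *d_p*:

  ```
  tapering = 100 · (d_p − d) / d_p   [%]
  ```

  Healthy airways narrow distally (positive tapering ≈ 25–30%); airways
  tethered open by fibrosis (traction bronchiectasis) fail to narrow, so
  *reduced* tapering is the disease signature.

* **Segmental tortuosity** of a segment with centreline arc length *L_a*
  and straight end-to-end distance *L_e*:

  ```
  tortuosity = L_a / L_e   (≥ 1; 1 for a straight airway)
  ```

  Fibrotic retraction pulls airways into curved courses, increasing it.

* **Total segment count** — the number of airway segments identified on
  the CT.

Diameters come from the full-width-at-half-maximum (FWHM) edge-cued
technique: at each centreline sample (every half of the smallest voxel
dimension), a CT slice perpendicular to the airway (at most 40 × 40 mm) is
interpolated; radial intensity profiles model the airway wall as a Gaussian,
place the inner lumen boundary at the inner half-maximum point, and a direct
least-squares ellipse over the boundary points yields the geometric-mean
diameter `2·√(r_minor · r_major)`.

A synthetic phantom module renders branching HU tube trees with analytic
ground truth (diameters, lengths, tortuosity, tapering, lobes), so the whole
pipeline is testable without clinical data. A cap-and-sum aggregator for
visually scored traction-bronchiectasis extent (max 16) and severity
(max 18) is included for comparison studies.

## Worked example

```python
import airquant as aq

spec = aq.build_standard_tree(child_ratio=0.75)   # uniform 25% narrowing
volume, mask, truth = aq.rasterize(spec)

graph = aq.build_airway_graph(mask)               # thinning -> rooted tree
aq.assign_generations(graph)                      # trachea = generation 0
aq.classify_lobes(graph)                          # RUL/RML/RLL/LUL/LML/LLL
aq.measure_graph(volume, graph)                   # FWHM ellipse calipers

summary = aq.summarize_patient(graph)
print(summary.median_intersegmental_tapering_pct,
      summary.median_tortuosity, summary.total_segment_count)
```

prints (up to caliper noise at the sub-voxel level):

```
25.59 1.0047 51
```

— the median tapering recovers the phantom's 25% per-generation narrowing
within one point, tortuosity is 1 to within 5·10⁻³ for an all-straight
tree, and all 51 rendered branches are found as segments.

The `examples/` directory holds one short narrative script per capability
(phantom + truth tables, single-airway calipers, the full pipeline, visual
score aggregation, airway maps). A thin CLI wraps the library:

```bash
airquant phantom --out demo --taper 0.25
airquant run --ct demo/ct.nii.gz --airway demo/airway.nii.gz --out demo/run
airquant report demo/run
```

`airquant run` writes `segments.csv`, `patient_summary.csv`,
`graph.graphml`, an airway-map PNG (edge width ∝ diameter, colour = lobe),
a stage-count run log, and the resolved config; re-running from that config
reproduces the CSVs byte for byte.

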