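"""Run the complete quantification pipeline on a phantom case.

Writes the phantom to NIfTI, then runs mask clean-up -> skeleton ->
airway graph -> lobe/generation labels -> calipers -> biomarkers, and
prints the per-patient summary: median intersegmental tapering and
median segmental tortuosity over airway generations 2-6, plus the total
segment count.
"""

import tempfile
from pathlib import Path

import pandas as pd

import airquant as aq
from airquant.report import RunConfig, run_pipeline

tmp = Path(tempfile.mkdtemp())
spec = aq.build_standard_tree(child_ratio=0.75, amplitude_mm=1.0, max_generation=5)
volume, mask, truth = aq.rasterize(spec)
aq.save_volume(volume, tmp / "ct.nii.gz")
aq.save_mask(mask, tmp / "airway.nii.gz")

config = RunConfig(
    ct_path=str(tmp / "ct.nii.gz"),
    airway_path=str(tmp / "airway.nii.gz"),
    out_dir=str(tmp / "out"),
    patient_id="phantom01",
)
out = run_pipeline(config)
summary = pd.read_csv(out / "patient_summary.csv")
print(summary.to_string(index=False))
print(f"\noutputs in {out}: segments.csv, patient_summary.csv, graph.graphml, "
      "airway_graph.png, run_log.json, config.json")

# Median tapering near 25 reflects the phantom's uniform 25% child
# narrowing; reduced values would signal traction bronchiectasis.
# Tortuosity slightly above 1 reflects the 1 mm sinuosity of the branches.
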