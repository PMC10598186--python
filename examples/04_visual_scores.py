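"""Aggregate radiologist traction-bronchiectasis scores per patient.

Extent counts involved airway segments per lobe and is capped at 3 in
upper/lower lobes and 2 in the middle lobes (whole-lung maximum 16);
severity is a 0-3 grade per lobe (maximum 18). The lingula counts as a
sixth lobe in place of a left middle lobe.
"""

import pandas as pd

from airquant.visual_scores import aggregate_table

raw = pd.DataFrame(
    [
        # patient p1: florid disease, every lobe saturates its cap
        *({"patient_id": "p1", "lobe": l, "kind": "extent", "value": 9}
          for l in ("RUL", "RML", "RLL", "LUL", "LML", "LLL")),
        *({"patient_id": "p1", "lobe": l, "kind": "severity", "value": 3}
          for l in ("RUL", "RML", "RLL", "LUL", "LML", "LLL")),
        # patient p2: mild basal disease
        {"patient_id": "p2", "lobe": "RLL", "kind": "extent", "value": 2},
        {"patient_id": "p2", "lobe": "LLL", "kind": "extent", "value": 1},
        {"patient_id": "p2", "lobe": "RLL", "kind": "severity", "value": 1},
        {"patient_id": "p2", "lobe": "LLL", "kind": "severity", "value": 1},
    ]
)
print(aggregate_table(raw).to_string(index=False))
# p1 hits the published maxima (extent 16, severity 18); p2 sums its raw
# sub-cap scores (extent 3, severity 2).
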