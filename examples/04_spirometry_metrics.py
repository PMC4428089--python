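"""Spirometry-derived weakness indicators on a small cohort table.

The postural drop dFVC = (FVC_sit - FVC_sup)/FVC_sit * 100% measures how
much vital capacity is lost lying down; a drop above 25% suggests
diaphragmatic weakness, and expiratory CO2 above 6.0 kPa suggests
chronic alveolar hypoventilation.  Both flags are strict (boundary
values do not flag).
"""

import pandas as pd

from lungmorph import load_cohort, postural_drop

rows = [
    # subject, group, FVC sitting, FVC supine (%pred), CO2 (kPa)
    ("P01", "patient", 60.0, 43.0, 6.4),
    ("P02", "patient", 45.0, 27.0, 5.2),
    ("P03", "patient", 84.0, 70.0, 5.9),
    ("C01", "control", 102.0, 102.0, 5.0),
    ("C02", "control", 92.0, 87.0, 4.8),
]
frame = pd.DataFrame(rows, columns=["subject_id", "group", "fvc_sitting_pct",
                                    "fvc_supine_pct", "co2_kpa"])
table = load_cohort(frame)

cols = ["subject_id", "group", "delta_fvc_pct", "weakness_flag",
        "hypercapnia_flag"]
print(table.frame[cols].to_string(index=False,
                                  float_format=lambda v: f"{v:.1f}"))
print(f"\nworked check: postural_drop(60, 43) = {postural_drop(60, 43):.2f}%"
      " -> above the 25% weakness threshold")
# The formula is scale invariant: percent-predicted and litre inputs
# give the same drop.
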