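"""From raw decay stacks to the QC-filtered single-cell OMI feature table.

Simulates one field per condition, runs segmentation, per-pixel fitting,
CD69 assignment and feature aggregation, applies the quality-control
rules, and prints the per-group means of the key metabolic variables.
"""

import pandas as pd

from lymphomi import SimConfig, apply_qc_filters, simulate_field
from lymphomi.features import normalize_orr
from lymphomi.pipeline import analyze_field

config = SimConfig(image_size=(128, 128), n_cells=10, cell_radius_px=(5.0, 7.0))
tables = []
for seed, condition in ((1, "control"), (2, "stimulated")):
    field = simulate_field(config, condition, seed=seed, batch_id="day0")
    tables.append(analyze_field(field).features)
features = pd.concat(tables, ignore_index=True)

# QC: drop dim cells (< 5,000 photons) and masks too small to be cells
# (the area rule is relaxed here because this demo uses small cells)
features, excluded = apply_qc_filters(features, min_area_px=50)
features = normalize_orr(features, batch_col="batch_id")
print(f"{len(features)} cells pass QC; exclusions: {excluded}")

summary = features.groupby("activation")[
    ["nadh_tm", "nadh_a1", "fad_tm", "orr_norm"]
].mean().round(3)
print(summary.to_string())
# Expected pattern for activated vs quiescent lymphocytes: higher NAD(P)H
# alpha1 (more free NAD(P)H), lower NAD(P)H tau_m, higher redox ratio --
# the metabolic signature of a shift toward glycolysis.
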