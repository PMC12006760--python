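"""Simulate a small FLIM field and recover decay parameters by refitting.

Builds one synthetic NAD(P)H/FAD acquisition (128 x 128 px, 12 cells),
fits the bi-exponential reconvolution model at every foreground pixel,
and compares the per-cell fitted values with the simulator's ground truth.
"""

import numpy as np

from lymphomi import SimConfig, fit_image, simulate_field
from lymphomi.fitting import default_fit_config

config = SimConfig(image_size=(128, 128), n_cells=12, cell_radius_px=(5.0, 7.0))
field = simulate_field(config, condition="stimulated", seed=1)
truth = field.ground_truth

print(f"simulated {len(truth)} cells, "
      f"{field.nadh.counts.sum():.2e} NAD(P)H photons in the field")

result = fit_image(field.nadh, field.irf, default_fit_config("nadh"))
fitted = np.isfinite(result.tau_m)
print(f"fitted {fitted.sum()} foreground pixels "
      f"(intensity threshold {result.intensity_threshold:.0f} photons)")

for _, cell in truth.head(3).iterrows():
    in_cell = field.cell_mask == cell.cell_id
    tm_fit = np.nanmean(result.tau_m[in_cell])
    a1_fit = 100 * np.nanmean(result.a1[in_cell])
    print(
        f"cell {cell.cell_id}: tau_m fit {tm_fit:.3f} ns vs true {cell.nadh_tm:.3f} ns; "
        f"alpha1 fit {a1_fit:.1f}% vs true {100 * cell.nadh_a1:.1f}%"
    )

# tau_m is the amplitude-weighted mean lifetime; close agreement between the
# fitted and true values shows the reconvolution fit undoes the IRF blur and
# the Poisson noise at these photon budgets.
print(f"median reduced chi2: {np.nanmedian(result.chi2):.3f} (1.0 = ideal fit)")
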