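# lymphomi

Label-free **optical metabolic imaging (OMI)** analysis of lymphocyte
activation. The package turns time-domain fluorescence-lifetime (FLIM)
image stacks of the metabolic cofactors NAD(P)H and FAD into single-cell
metabolic feature tables and classifies **activated vs quiescent** B and
NK cells — and ships a synthetic-data generator that emulates the
microscope, so the whole pipeline runs and is tested without any external
data.

It is written for microscopists and computational biologists who work with
TCSPC (time-correlated single photon counting) FLIM data and want an open,
scriptable version of the standard OMI workflow:

1. **simulate / ingest** — photon-count stacks (x, y, time-bin) per
   channel, an instrument response function (IRF), a CD69 marker image and
   cell masks;
2. **fit** — per-pixel bi-exponential reconvolution,
   `I(t) = IRF ⊛ (α₁e^(−t/τ₁) + α₂e^(−t/τ₂)) + C`, with spatial binning to
   a ≥100-photon peak, periodic (80 MHz) wrap-around, and reduced-χ²
   goodness of fit; the mean lifetime is the amplitude-weighted
   `τₘ = (α₁τ₁ + α₂τ₂)/(α₁ + α₂)`;
3. **phasor** — fit-free coordinates `G = Σ I(t)cos(ωt)/ΣI(t)`,
   `S = Σ I(t)sin(ωt)/ΣI(t)` at ω = 2πnf (n = 1, 2; f = 80 MHz), with IRF
   calibration by polar scale-and-rotation;
4. **features** — per-cell cytoplasm means of the nine OMI variables
   (NAD(P)H and FAD τₘ, τ₁, τ₂, α₁%, plus the optical redox ratio
   `ORR = I_NAD(P)H/(I_NAD(P)H + I_FAD)` normalized to each batch's
   quiescent controls), CD69 assignment by 75% mask overlap, and QC
   filters (≥5,000 photons, ≥250 px, pixel χ² ≤ 1.3);
5. **classify / report** — z-score Ward clustering, seeded UMAP, a
   100-tree random forest on the nine variables (70/30 split), phasor
   classifiers (logistic and random forest, 50/50 split), Glass's-Delta
   effect sizes `Δ = (µ_control − µ_test)/σ_control` and
   coefficient-of-variation heterogeneity summaries.

## Worked example

```python
import numpy as np
from lymphomi import SimConfig, simulate_field, fit_image
from lymphomi.fitting import default_fit_config

config = SimConfig(image_size=(128, 128), n_cells=12, cell_radius_px=(5.0, 7.0))
field = simulate_field(config, condition="stimulated", seed=1)
result = fit_image(field.nadh, field.irf, default_fit_config("nadh"))

cell = field.ground_truth.iloc[0]
in_cell = field.cell_mask == cell.cell_id
print(f"tau_m fit {np.nanmean(result.tau_m[in_cell]):.3f} ns "
      f"vs true {cell.nadh_tm:.3f} ns")
print(f"median reduced chi2 {np.nanmedian(result.chi2):.3f}")
```

prints (seed 1):

```
tau_m fit 0.999 ns vs true 1.000 ns
median reduced chi2 1.194
```

— the refitted amplitude-weighted mean lifetime matches the simulated
cell's ground truth to a few milliseconds of a nanosecond, and a reduced
χ² near 1 says the Poisson noise model is calibrated. The scripts in
`examples/` walk through each capability the same way (simulation + fit,
phasor geometry, feature extraction, classification); each prints the
numbers it computes and what they mean.

Running the default synthetic activation study end to end
(`lymphomi.pipeline.run_synthetic_study`: 2 conditions × 3 batches × 2
fields of 55 cells, ~600 CD69-labeled cells) gives a 9-variable
random-forest test accuracy of ~0.98 with NAD(P)H α₁ carrying the largest
importance — the configured activation shift (Glass's Δ ≈ 2.9 on α₁, with
higher redox ratio and lower τₘ) is exactly the metabolic signature the
classifier should find.

## Command line

A thin CLI wraps the staged pipeline (each stage reads and writes open
formats: multi-page TIFF + JSON sidecars, 16-bit label TIFFs, CSV tables,
JSON reports, plus a run manifest with file hashes):

```bash
lymphomi run-all --out-dir runs/demo --seed 1
lymphomi simulate --config config.yaml --out-dir runs/demo --seed 1
lymphomi classify --out-dir runs/demo --seed 1
```

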