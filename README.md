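# vsimetry

Vessel size imaging (VSI) from spin-and-gradient-echo (SAGE) EPI
dynamic-susceptibility-contrast MRI, with quantitative histology
morphometry and MRI-vs-histology agreement statistics.

Gradient-echo DSC contrast (ΔR2\*) is sensitive to vessels of all
calibers while spin-echo contrast (ΔR2) is capillary-weighted, so their
ratio carries information about average vessel size. `vsimetry` is aimed
at perfusion-MRI researchers who want a testable, end-to-end
implementation of that idea: every processing stage can be exercised on
synthetic data with exact ground truth.

## What it computes

**Four-echo SAGE inversion.** A SAGE-EPI shot measures two gradient
echoes (TE₁, TE₂), an asymmetric spin echo (TE₃) and the spin echo
(TE₄). The log-signals are linear in `A = [ln S₀, ln δ, R2*, R2]`
(δ absorbs the pre/post-refocusing slice-profile mismatch):

```
ln S = Y·A,   Y = [[1,  0, −TE₁,        0       ],
                   [1,  0, −TE₂,        0       ],
                   [1, −1, −TE₄+TE₃,    TE₄−2·TE₃],
                   [1, −1,  0,         −TE₄      ]]
```

The system is exactly determined, so per-voxel, per-timepoint rates come
from a single matrix solve (`SageInverter`, a scikit-learn-style
transformer).

**Perfusion and diffusion maps.** rCBV is the trapezoidal integral of
the leakage-corrected ΔR2\*(t) curve, normalized to contralateral
normal-appearing white matter (NAWM mean = 1); leakage correction is a
Boxerman-family linear model with unidirectional or bidirectional
(backflux) terms. ADC comes from an OLS log-linear fit over b-values
(default 0/500/1000 s/mm²), in μm²/ms.

**Vessel size index.** With rates in ms⁻¹ and ADC in μm²/ms,

```
VSI [μm] = 0.867 · √(rCBV·ADC) · ΔR2*max / ΔR2max^{3/2}
```

**Histology morphometry.** Stained sections are segmented by
seed-and-grow HSV classification, morphologically refined (join / close /
split multi-lumen / hole fill), and summarized as vessel density (N/mm²)
and the randomly-oriented-cylinder caliber

```
VSI_histo = ( Σ n(rᵢ)·rᵢ^{4/3} / Σ n(rᵢ)·rᵢ² )^{−3/2}
```

**Agreement statistics.** Median map values over 5-mm-radius spherical
biopsy targets are paired with per-target histology and compared with
Pearson correlation, Bland–Altman limits of agreement (±1.96 sample SD),
Mann–Whitney grade comparisons, Shapiro–Wilk normality checks and a
paired t-test.

A synthetic-data layer (`vsimetry.synthetic`) generates SAGE/DWI
phantoms, stained-slide images and paired cohorts with known ground
truth for all of the above.

## Worked example

```python
import numpy as np
from vsimetry.synthetic import PhantomSpec, BolusModel, simulate_sage_dataset, simulate_dwi
from vsimetry import fit_sage_series, delta_curves, compute_cbv, normalize_cbv, fit_adc, compute_vsi

phantom = PhantomSpec(grid_shape=(32, 32, 8), noise_sigma=0.0)
sim = simulate_sage_dataset(phantom, BolusModel(), n_timepoints=60)
truth = sim.truth

series = fit_sage_series(sim.signal, mask=truth.labels > 0)
rel = delta_curves(series)                      # baseline-referenced ΔR2*(t), ΔR2(t)
cbv = compute_cbv(np.nan_to_num(rel.d_r2star_t), truth.time_axis_s)
rcbv = normalize_cbv(cbv, truth.labels == 1)    # NAWM-normalized
adc = fit_adc(simulate_dwi(truth.adc, truth.s0))
vsi = compute_vsi(rcbv, adc, rel.d_r2star_max, rel.d_r2_max)

tumor = truth.labels == 2
print(f"tumor median rCBV {np.nanmedian(rcbv[tumor]):.2f}")
print(f"tumor median ADC  {np.nanmedian(adc[tumor]):.2f} um^2/ms")
print(f"tumor median VSI  {np.nanmedian(vsi.vsi[tumor]):.2f} um "
      f"(ground truth {phantom.classes['tumor'].true_vsi(2.0):.2f} um)")
```

prints

```
tumor median rCBV 2.00
tumor median ADC  1.30 um^2/ms
tumor median VSI  12.68 um (ground truth 12.50 um)
```

i.e. the pipeline recovers the phantom's tumor-class vessel caliber to
about 1.4% — the residual comes from discrete sampling and smoothing of
the bolus peak, not from the inversion, which is exact.

A full multi-stage run (simulation → relaxometry → perfusion → VSI →
histology → validation, with per-stage provenance manifests) is driven
by a YAML config:

```bash
vsimetry run --config "$(vsimetry demo-config)" --out demo_run
```

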