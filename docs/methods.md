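# Methods

This note records the models, numerical choices and limitations behind
`vsimetry`, in the spirit of a methods appendix.

## Signal model and inversion

A SAGE-EPI readout acquires, per shot, two gradient echoes (TE₁, TE₂),
an asymmetric spin echo (TE₃) and the spin echo (TE₄), with
TE₃ > TE₄/2. Assuming monoexponential transverse decay, the four log
signals are linear in `A = [ln S₀, ln δ, R2*, R2]`:

- `ln S₁ = ln S₀ − TE₁·R2*`
- `ln S₂ = ln S₀ − TE₂·R2*`
- `ln S₃ = ln S₀ − ln δ − (TE₄−TE₃)·R2* − (2TE₃−TE₄)·R2`
- `ln S₄ = ln S₀ − ln δ − TE₄·R2`

δ is the multiplicative residual between the pre- and post-refocusing
echo trains caused by imperfectly matched slice profiles; it is fitted
jointly rather than assumed away. The 4×4 system is exactly determined,
so the inversion is `A = Y⁻¹ ln S` — no least squares, no iteration, and
the forward→inverse round trip is exact to floating-point precision
(the test suite checks ≤1e−9 relative error over random parameter
draws). Voxels with any non-positive signal are masked (NaN), not
raised, so volume-scale fitting never aborts on noise floor voxels.
`fit_sage_series` reports the invalid-fit fraction and a δ-stability
diagnostic (median over voxels of the max percent variation of δ over
time); the diagnostic has no hard threshold — on noiseless data it is 0,
and it grows with thermal noise because the exactly-determined solve
amplifies per-echo noise into ln δ.

Units: all rates are ms⁻¹ and echo times ms throughout. Combined with
ADC in μm²/ms this makes the vessel size index come out in μm with no
hidden conversion factors.

## Bolus dynamics and peak extraction

ΔR(t) = R(t) − mean(R over a pre-bolus baseline window), for both rates.
The default baseline window runs from timepoint 5 to three samples
before bolus arrival, where arrival is the first timepoint exceeding the
provisional baseline mean by 5 SD — standard DSC practice. A window
that extends past the detected arrival is refused (warning + error)
rather than silently producing biased baselines.

Peaks ΔR2\*max, ΔR2max are the post-baseline maxima of the Δ-curves,
taken independently per rate, after an optional 3-point moving average
(default on). Voxels whose peaks are not positive are masked invalid
instead of clipped to zero, so they cannot enter the VSI map as fake
zero-caliber tissue. The alternative convention of reading ΔR2 at the
ΔR2\* peak time is deliberately not the default: with a shared bolus
shape the two conventions agree, and independent maxima are the more
conservative reading when the shapes differ.

## rCBV, leakage correction, ADC

Raw CBV is the trapezoidal integral of ΔR2\*(t) over the full
post-arrival window (including recirculation, consistent with the
leakage model's assumption; a first-pass-only window is configurable).
rCBV divides by the mean over a user-supplied NAWM mask, so the NAWM
mean is 1 by construction; normalization is idempotent and invariant to
positive rescaling of the raw map. Note rCBV is a *relative* blood
volume — using it inside the VSI formula approximates the absolute
blood volume up to the NAWM calibration, a known caveat of the model.

Leakage correction is a Boxerman-family linear model. Each voxel curve
is regressed on a reference curve R(t) (mean ΔR2\*(t) over non-leaky
tissue) and a leakage term
`L(t) = ∫₀ᵗ R(τ)·exp(−k_back(t−τ)) dτ`:
`meas = K1·R − K2·L`. `k_back = 0` is the unidirectional (efflux-only)
form; bidirectional mode picks `k_back` per voxel from a small grid
(0–0.05 s⁻¹) by residual, which lets tracer return to the vasculature.
The corrected curve is `meas + K2·L`, preserving voxel-specific
deviations from the reference shape. The default mode is bidirectional.
This is a standard-form implementation chosen on purpose; it is a
two-to-three-parameter linear model, not a pharmacokinetic fit.

ADC is the negated OLS slope of ln S against b over ≥2 distinct
b-values (default 0/500/1000 s/mm²), converted to μm²/ms
(1 μm²/ms = 10⁻³ mm²/s).

## Vessel size index

`VSI = k·√(rCBV·ADC)·ΔR2*max / ΔR2max^{3/2}` with k = 0.867 by default.
k is exposed as a parameter because the proportionality constant has not
been thoroughly validated against tissue. The exponent grouping is
ΔR2\* over (ΔR2)^{3/2}; the alternative reading (ΔR2\*/ΔR2)^{3/2} is
dimensionally wrong under this unit convention and is not offered.
Voxels are invalid where the ΔR2 peak is ≤ 0 or where rCBV·ADC < 0; a
zero factor (e.g. rCBV = 0) yields a valid VSI of 0. VSI is strictly
increasing in ΔR2\* and in rCBV·ADC, strictly decreasing in ΔR2, and
scales as c^{−1/2} when both peaks scale by c — all property-tested.

## Histology morphometry

Segmentation emulates hue-based chromogen analysis: pixels firmly
inside the vessel hue range (wrapped red-brown interval, high
saturation) seed a region growing implemented as morphological
reconstruction into a looser saturation/value tolerance — i.e. growth is
restricted to seed-connected pixels. Degenerate color models (no
saturation anywhere, or a tolerance covering the whole image) are
refused explicitly.

Refinement performs, in order: joining objects whose gap is below
`join_distance` (default 5 μm, as a closing of half that radius);
closing narrow peripheral gaps (`closing_radius` 2 px); splitting
objects that enclose ≥2 lumens of at least `min_lumen_area` (10 px²)
along the watershed between lumens; and hole-filling so lumen area
counts toward vessel area. These three defaults are not dictated by any
printed protocol; they are exposed in the config and documented here.
Interactive manual correction is replaced by an optional override mask.

Vessel radius is the equivalent-circle radius of the filled object
(minor-axis/2 is available for oblique sections). The section-level
caliber is `(Σ n(rᵢ)rᵢ^{4/3} / Σ n(rᵢ)rᵢ²)^{−3/2}`, the
randomly-oriented-cylinder summary; it equals r for monodisperse radii,
scales linearly with the radii, and always lies between the extreme
radii. (It is algebraically identical to the form
`(Σr²/Σr^{4/3})^{3/2}` seen elsewhere; only the exponent placement
differs.) Density is object count over analyzed field area. Per-target
values average 3 ROIs (non-overlapping random tiles by default, hotspot
ranking optional); ROI counts sum and densities/calibers average
arithmetically.

## Target extraction and statistics

Biopsy targets are spheres (default radius 5 mm) in the scanner frame;
membership is by voxel-center distance, with no partial-volume
weighting, so a brute-force enumeration oracle can verify it. The MRI
summary per target is the median over valid in-sphere voxels (mean
optional).

Bland–Altman uses the sample SD (n−1) and reports mean ± 1.96 SD limits.
In the cohort report the difference is taken as VSI_histology −
VSI_MRI, so a negative mean difference means MRI overestimates caliber.
Pearson r carries the two-sided t-distribution p with n−2 df.
Mann–Whitney U is exact for small untied samples (normal approximation
with tie correction otherwise). The t-test on the caliber difference is
paired by default — the data are paired per target — with an unpaired
variant available. Degenerate inputs (zero-variance differences) return
the limiting p-values (1 for zero mean, 0 otherwise) rather than NaN.

## Synthetic data: what it does and does not emulate

The phantom is a labeled grid (background / NAWM / tumor sphere) whose
classes carry baseline R2\*/R2, S₀, δ, ADC, bolus peak effects and an
optional leakage rate. ΔR2\*(t) and ΔR2(t) are a shared unit-peak
gamma-variate bolus scaled by the class peaks, so the GE/SE ratio — and
hence the ground-truth VSI — is constant and known per class. Leakage
enters ΔR2\*(t) as −(rate)·∫b, the same linear form the correction
models, which makes correction exactly verifiable. Defaults: bolus
arrival 24 s, shape α=3, β=4 s (peak at 36 s, width realistic for an
intravenous bolus sampled at TR = 2 s); tumor ADC 1.30 μm²/ms and a 2×
NAWM blood-volume scale, i.e. true tumor rCBV 2 and a tumor-class VSI
of 12.5 μm — values at the scale reported for high-grade glioma tissue.

Simplifications to keep in mind when interpreting green tests: noise is
additive Gaussian per echo, not Rician (at simulated SNR the log-domain
inversion does not see the difference, but very low-signal regimes are
not represented); there is no arterial input deconvolution, partial
volume, B₀/B₁ imperfection or EPI distortion; rendered vessels are
perpendicular circular sections (oblique ellipses behind a flag) and
slides carry no stain variability beyond seeded value/saturation
jitter. Passing tests demonstrate correctness of the computations and
internal consistency of the model chain — not robustness to artifacts
the simulator does not produce.

Cohort generation draws paired (rCBV, density) and (VSI_MRI,
VSI_histology) values from bivariate normal models with requested
correlations at in-vivo scale (n = 26 targets; rCBV 1.39 ± 0.55,
density 40.6 ± 18 /mm², calibers ≈ 13.7/12.6 ± ~2 μm; SDs set from
reported interquartile ranges as IQR/1.35). Values are floored at small
positive bounds; at these means the truncation is negligible.

## Problem sizes and numerical tolerances

The test suite and the acceptance script use a 32×32×8 grid with 60
timepoints for end-to-end recovery (recovered tumor-class median VSI
within 5% of truth; measured ≈1.4%, attributable to discrete bolus
sampling plus 3-point smoothing of the peak, since the inversion itself
is exact), 1024² px slides with 50 vessels for the segmentation oracle
(exact count; radius within max(1 px, 5%)), and 500 seeded cohorts of
26 targets for statistics recovery (mean r inside the Fisher-z CI of
ρ=0.5; type-I rate of the correlation test within [0.03, 0.07] at
nominal 0.05). These sizes were chosen as the smallest that exercise
every code path with stable statistics.

## Pipeline and provenance

`vsimetry run` executes configured stages into one run directory. Each
stage writes a manifest (parameters, seed, package version, SHA-256 of
all inputs and outputs); consumers re-hash their inputs against the
producer's manifest and fail loudly on mismatch. Seeds for every
stochastic stage derive from the single config seed, so a rerun is
bit-identical. Configuration is YAML validated through typed pydantic
models; stages must appear in dependency order.

## Known limitations

- Image registration between MRI spaces is out of scope; targets are
  interpreted in the coordinate frame of the maps they index.
- NAWM masks are user-supplied (or phantom labels); no automatic NAWM
  detection.
- The leakage model is linear; genuinely pharmacokinetic behavior
  (nonlinear extraction, T1 dominance) is outside its span.
- `delta_curves` assumes a single dominant bolus; multi-injection
  protocols would need explicit baseline windows.
- VSI validity requires a positive spin-echo peak; in low-SNR tissue
  large invalid fractions are expected and are reported, not hidden.
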