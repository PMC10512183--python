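# Methods

This note documents the models, parameter choices, and numerical decisions
behind fibrospec, and what its synthetic validation does and does not show.

## The synthetic cohort generator

The generator (`fibrospec.synthesis`) emulates an FTIR imaging study of three
groups of cultured skin fibroblasts (labels CTRL / MS / ALS, 10 samples per
group by default) measured over 950–3500 cm⁻¹. It is a *statistical* emulator:
it reproduces the structure the pipeline must cope with, not the physics of an
interferometer.

**Spectral model.** A cell spectrum is a sum of Gaussian bands. The control
template has 15 bands whose centers sit inside the standard assignment
regions (Amide A/B/I/II/III, the four C–H stretches, carbonyl ester at
1738 cm⁻¹, acyl sub-peaks at 1455 and 1435 cm⁻¹, amide III, and two
mixed-region bands), with amplitudes making Amide I dominant, as in measured
fibroblast spectra. Band σ values (6–40 cm⁻¹) follow typical mid-IR
bandwidths: narrow CH-deformation bands, broad N–H/O–H envelopes.

**Group effects.** A `GroupEffect` perturbs the template by per-band
amplitude multipliers, center shifts (bounded ±15 cm⁻¹), and dropped bands.
The default disease-like templates encode the qualitative pattern of the
biology they emulate: carbonyl ester down (MS ×0.8, ALS ×0.85), Amide I up in
MS (×1.15), Amide II and CH₂ stretches down in ALS, Amide I center +4 cm⁻¹ in
both, and the 1435 cm⁻¹ acyl sub-peak dropped in both (single acyl peak).
The multipliers are plausible placeholders chosen once for power studies, not
estimates of real effect sizes — no quantitative effect sizes are available
to calibrate against.

**Nuisance terms and defaults** (units AU = absorbance units):

| parameter | default | meaning |
|---|---|---|
| `axis_step` | 4 cm⁻¹ | point spacing (instrument resolution 8 cm⁻¹; spacing is a choice, flagged in config) |
| `n_rows × n_cols` | 16×16 | image size; desk-scale stand-in for a full FPA mosaic (pipeline behavior is geometry-independent) |
| `background_fraction` | 0.4 | background pixels per image (round-half-even ⇒ 102 of 256) |
| `baseline_coeffs` | (0.05, 0.02, 0.01) | polynomial drift in the scaled coordinate, per-image jitter SD 0.01 |
| `co2_band` | 2350 cm⁻¹, σ 12, amp 0.15 | atmospheric artifact, added to every pixel |
| `mie_amplitude`, `mie_period` | 0.03 AU, 1800 cm⁻¹ | per-cell-pixel sinusoidal ripple with random phase; 1800 cm⁻¹ lies in the van de Hulst oscillation band 1/(2r(m−1)) ≈ 1250–5000 cm⁻¹ for the modeled sphere grid |
| `noise_sd` | 0.005 AU | per-pixel white noise (~1–2 % of the Amide I peak) |
| `between_sample_sd` | 0.08 | log-normal per-sample global scale (biological abundance variability; cancels in ratios) |
| `band_jitter_sd` | 0.05 | log-normal per-sample, per-band amplitude jitter — the band-level biological variability that makes ratio ANOVA non-degenerate |

Everything is a pure function of the config: per-sample seeds are spawned
from `config.seed` via `SeedSequence`, so cohorts are bit-reproducible.

**Two fidelity levels.** `generate_cohort` produces full images (the input of
the preprocessing chain). `generate_cohort_spectra` draws per-sample mean
spectra directly, with noise scaled by 1/√n_cell as a pixel average would be,
then applies the tail of the chain (excision, SG smoothing, normalization,
derivative). It exists for calibration and power studies that need thousands
of cohorts; it deliberately omits baseline drift, ripple, and segmentation
error, so conclusions drawn from it concern the statistics downstream of
preprocessing, not the preprocessing itself.

**What passing tests do not show.** The generator has no water-vapor lines,
detector nonlinearity, focal-plane vignetting, spatial correlation between
pixels, or realistic cell morphology; band shapes are exactly Gaussian and
group differences exactly follow the effect template. Passing the recovery
tests therefore demonstrates that the pipeline is correct and calibrated
*under its own model class* — it does not certify performance on measured
patient spectra.

## Preprocessing

Stage order: excision → rubber-band baseline → segmentation → binning →
scatter correction → SG smoothing → averaging → vector normalization → SG
second derivative → vector normalization. Axes are stored strictly ascending
and carry explicit contiguity *segments*; after the 2000–2700 cm⁻¹ excision
every windowed operation runs per segment, so nothing bridges the gap
(verified by an oracle that processes segments standalone).

* **Rubber band** is the lower convex hull (Andrew monotone chain) per
  segment; the corrected spectrum is nonnegative with exact zeros at the hull
  support points. An O(n²) minimal-slope-walk oracle validates it.
* **Segmentation** uses Lloyd's algorithm with deterministic initial
  centroids at the (j+½)/k quantiles of total absorbance. This makes the
  mask a pure, permutation-equivariant function of the pixel spectra (a
  seeded k-means++ draw would not be); the higher-absorbance cluster is
  "cell" because cells absorb more than near-background.
* **Binning** defaults to 2×2 *spatial* pixel binning (a block containing
  cell pixels averages only those). Spectral binning (adjacent axis points,
  trailing remainder kept as a smaller bin) is available via
  `bin_mode="spectral"`. Spatial is the default because image binning is
  what the reduce-file-size step does in the imaging toolchain this mirrors,
  and because halving the spectral sampling to 8 cm⁻¹ would make the
  1455/1435 cm⁻¹ acyl sub-peak pair unresolvable under the prescribed
  window-7 second derivative — defeating the peak-count analysis.
* **Scatter correction** is clustered, non-iterative EMSC. The Mie basis is
  the first 7 principal directions of van de Hulst extinction curves over a
  10×10 grid of sphere radius 2–8 µm and refractive index 1.1–1.5. Spectra
  are clustered (same deterministic k-means, 5 clusters) and each cluster is
  solved in one batched least squares; since the model is linear and
  non-iterative this equals per-spectrum fits, and the clustering mirrors
  the clustered-correction structure at equal cost. Spectra whose fitted
  reference coefficient a ≤ 10⁻⁶ are passed through and flagged
  uncorrectable. In `emsc_poly` mode (no Mie basis) the correction is
  idempotent on its own output. One caveat is documented and tested: with a
  protein/carbohydrate gel reference, EMSC legitimately absorbs a little of
  the genuine lipid-band structure into its nuisance terms (cosine to truth
  ≈ 0.99 rather than 1.0 on degenerate noise-free samples).
* **Savitzky–Golay** is implemented as a local least-squares polynomial fit
  in the physical wavenumber coordinate: derivative outputs are in AU·cm²
  independent of binning, non-uniform spacing (remainder bins) is handled
  exactly, and edge points are fitted on the truncated window. On uniform
  axes it matches `scipy.signal.savgol_filter` to 10⁻¹². It is exact on
  polynomials up to the fit order (2a on quadratics). For bands narrow
  relative to the window the quadratic fit underestimates curvature — about
  30 % for σ = 10 cm⁻¹ at window 7/step 4 — which is inherent to the filter
  and irrelevant for *positions* of minima; the analytic-derivative
  agreement test therefore uses a band wide relative to the window (σ = 50,
  bias ≈ 1.5 %).
* **Vector normalization** divides by the Euclidean norm (both after
  averaging and after differentiation, in that order).

The robustness preset `ALT_DERIV_PRESET` (window 15, order 5) is one flag
away; it changes the second derivative but not the mean absorbance.

## Band quantification

Areas are trapezoids over axis points inside the closed region (bounds snap
to measured points; no endpoint interpolation, so adjacent regions sharing a
grid point integrate additively). Ratios are numerator/denominator areas per
sample and are invariant to any global rescaling, normalization included.
The ratios quoted by single wavenumbers in the lipid-order literature
(~2920/2870 etc.) are implemented as ratios of the integrated C–H-stretch
regions containing those wavenumbers, since areas — not point intensities —
are what the workflow integrates.

Peak analysis finds local minima of the second-derivative trace in a region,
subject to (i) prominence ≥ 5 % of the region's dynamic range (a noise guard;
configurable), and (ii) a negative trace value — absorption bands are
negative second-derivative lobes, whereas the shallow dips midway between
well-separated bands hover at or above zero and are not bands. Positions are
refined by a 3-point parabola through the minimum (standard sub-grid
band-position practice; without it positions quantize to the axis step and a
4 cm⁻¹ shift would be invisible at 4–8 cm⁻¹ sampling). `refine=False` gives
grid-snapped positions. Shift analysis tracks the deepest minimum per sample
(ties to lower wavenumber), summarizes per group, and reports shifts as
non-reference minus reference (positive = toward higher wavenumber). Peaks
are analyzed per sample and then group-summarized.

## Group statistics

One-way ANOVA (classical between/within decomposition), Tukey HSD with the
Tukey–Kramer standard error for unequal n, q = |Δmean|/√(MSW(1/nᵢ+1/nⱼ)/2),
adjusted p from the studentized-range distribution (scipy). Brown–Forsythe is
ANOVA on |x − group median|; Shapiro–Wilk is the Royston AS R94
approximation (scipy). Diagnostics are reported, never used to gate the
ANOVA. Stars use strict thresholds (p = 0.05 exactly is "ns"). No
multiplicity correction across the 12-ratio panel by default, mirroring
per-ratio reporting conventions; Benjamini–Hochberg is available via
`bh_adjust=True`. A conservativeness guarantee is tested in its correct
form: Tukey adjusted p ≥ the unadjusted pooled-variance (Fisher LSD) t-test
p with |t| = q/√2 — the version against independent two-sample t-tests is
false in general because the variance estimates differ.

## Sparse PLS-DA

Labels are dummy-coded; X columns are centered and (by default)
unit-variance scaled — the toggle exists because scaling conventions vary
between toolchains. Constant columns are dropped with a warning. Per
component: dominant singular pair of X᷈ᵀY᷈; the X-weight is soft-thresholded
with λ equal to the (keep+1)-th largest magnitude, leaving exactly `keep_x[c]`
nonzeros, renormalized, and sign-fixed (largest-magnitude entry positive, for
run-to-run reproducibility); both X and Y are deflated by regression on
t = X᷈w (PLS2 regression mode — the single supported deflation, matching the
reference sparse-PLS formulation). With `keep_x = p` the model equals dense
NIPALS PLS-DA (scores to 10⁻⁸, up to sign — tested against an independent
NIPALS oracle).

Prediction projects new samples through R = W(PᵀW)⁻¹ and assigns the nearest
class centroid in Euclidean score distance (ties to the lexicographically
first class). Decision values Ŷ = T_new Qᵀ + ȳ feed the one-vs-rest AUROC,
computed through midranks (exactly the normalized Mann–Whitney U; ties count
½).

Tuning draws stratified fold assignments per repeat from a generator seeded
by (seed, repeat) — every candidate sees the same draws, so comparisons are
paired — and scores the balanced error rate (classes here are balanced, so
this equals overall error, but the criterion is declared). Selection is
sequential per component over the grid {5, 10, 20, 40, 60, 80} (the grid the
published selection of 60/40/20 retained variables plausibly came from is
not recorded anywhere, so a configurable default is provided); ties go to
fewer retained variables, then fewer components.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → preprocess → quantify → stats →
classify, writing every intermediate table as CSV with a fixed float format;
stage-specific child seeds are spawned from the global seed, so a config maps
to bit-identical outputs (tested byte-for-byte). Raw image cubes are written
only on request (`write_images=True`) — a full cohort is ~120 MB of CSV and
is bulk data, not an analysis artifact. CV repeats default to 50 in the desk
profile (the full protocol's 200 is one flag away); the acceptance script
uses 25 repeats for tuning, which is ample at n = 30. Config validation
collects *all* violations (source XOR, excision inside the axis, SG window
constraints, keep_x/grid vs available variables) rather than failing on the
first.

## Problem sizes used in validation

Unit and acceptance tests run the image pipeline at 8×8 to 16×16 pixels with
3–10 samples per group, and the spectrum-level generator for the large
repetition studies: 500 null panels for ANOVA type-I calibration, 200
simulations for effect-recovery power, 200 label permutations for AUROC
chance level. These sizes were chosen so the full suite completes in a couple
of minutes while keeping every Monte-Carlo margin of error several times
smaller than the tolerance it checks.

## Known limitations

* The EMSC reference-coefficient rescaling assumes the reference resembles
  the cell spectrum up to nuisance terms; a poor reference biases band
  amplitudes (see the gel-reference caveat above).
* The Mie correction is single-pass; no iterative resonant-Mie refinement.
* No atmospheric water-vapor compensation.
* The studentized-range p relies on scipy's numeric CDF; agreement with a
  10⁶-draw Monte-Carlo null is ~2–3 decimal places, which bounds the
  precision of quoted Tukey p values.
* Tuning explores a per-component grid sequentially, not the full product
  grid; a keep_x combination whose benefit only appears jointly across
  components would be missed.
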