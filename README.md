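# fibrospec

FTIR spectral phenotyping of cultured skin fibroblasts: a tested, reusable
pipeline for turning hyperspectral absorbance images of fixed cells into
per-sample spectra, band-ratio statistics, second-derivative peak positions,
and a sparse PLS-DA classification of disease-like groups.

## Who this is for

Vibrational-spectroscopy and chemometrics groups who profile cultured cells
(e.g. patient-derived fibroblasts from control, multiple-sclerosis-like, and
ALS-like donors) by FTIR microspectroscopy and need the full analysis chain
to be reproducible: pre-processing with declared parameters, area ratios with
proper univariate statistics, and a cross-validated multivariate classifier.
Because raw clinical spectra are rarely shareable, the package ships a
synthetic cohort generator that emulates the statistical structure of such a
study — cell and background pixels, baseline drift, a CO₂ artifact near
2350 cm⁻¹, Mie-like scatter ripple, group-specific band effects — so every
stage can be validated against known ground truth.

## The method

Per sample, an image of per-pixel absorbance spectra A(ν), ν ∈ [950, 3500] cm⁻¹,
is processed in the standard order:

1. **Excision** of 2000–2700 cm⁻¹ (CO₂ band, low biological signal); the gap
   is tracked so no later windowed operation bridges it.
2. **Rubber-band baseline**: subtract the lower convex hull of (ν, A).
3. **Segmentation**: k-means (k = 2) on pixel spectra; the cluster with the
   higher mean total absorbance is "cell".
4. **Binning** (default: 2×2 spatial pixel blocks).
5. **Scatter correction**: clustered EMSC — each spectrum is regressed on a
   reference spectrum plus a polynomial baseline and a PCA basis of
   van de Hulst Mie extinction curves Q(ρ) = 2 − (4/ρ)sin ρ + (4/ρ²)(1 − cos ρ),
   ρ = 4πr(m−1)ν, then rescaled by the fitted reference coefficient.
6. **Savitzky–Golay smoothing** (window 5, order 2), **pixel averaging**, and
   **vector normalization** → the mean absorbance spectrum.
7. **SG second derivative** (window 7, order 2) + renormalization → the
   second-derivative spectrum (band minima mark peak positions).

Downstream, trapezoidal band areas over the 14 standard assignment regions
(Amide A/B/I/II/III, C–H stretches, carbonyl ester ~1740 cm⁻¹, acyl chain
~1450 cm⁻¹, mixed 1300–1000 cm⁻¹) feed a 12-ratio panel tested per ratio by
one-way ANOVA with Tukey HSD (plus Shapiro–Wilk and Brown–Forsythe
diagnostics), and the second-derivative matrix feeds sparse PLS-DA: per
component the dominant singular vector of X᷈ᵀY᷈ is soft-thresholded to keep
exactly `keep_x[c]` wavenumbers, samples are classified by nearest class
centroid in score space, and `keep_x`/component count are tuned by repeated
stratified 3-fold cross-validation on the balanced error rate, with
one-vs-rest AUROC as the performance summary.

## Worked example

```python
import numpy as np
import fibrospec as fs

cfg = fs.SyntheticCohortConfig(seed=1)           # 3 groups x 10 samples
cohort, _ = fs.generate_cohort_spectra(cfg)      # spectrum-level cohort

panel = fs.compute_ratio_panel(cohort)
_, table = fs.ratio_panel_stats(panel)
print(table[["F", "p_anova", "stars", "p [CTRL vs MS]"]].head(4))
```

```text
                                  F   p_anova stars  p [CTRL vs MS]
ratio
Carbonyl ester/Total lipids   45.12  2.46e-09   ***       1.404e-09
Carbonyl ester/Acyl chain     42.49  4.57e-09   ***       6.153e-07
Carbonyl ester/Asymmetric CH3 51.34 6.305e-10   ***       4.581e-10
Amide I/Amide II              16.35 2.222e-05   ***       6.326e-05
```

The injected disease-like effects (carbonyl ester ×0.8, Amide I ×1.15) are
flagged with the correct directions. The classifier and the peak-shift
analysis on the same cohort:

```python
X = cohort.matrix("second_derivative")
y = np.asarray(cohort.groups)
res = fs.splsda_fit(X, y, 3, [60, 40, 20])
print(res.summary())

region = {r.name: r for r in fs.default_band_table()}["Amide I"]
print(fs.compare_peak_positions(cohort, region))
```

```text
Sparse PLS-DA (centroid distance)
========================================
samples: 30   variables: 463 (463 non-constant)
classes: ALS, CTRL, MS
components: 3   keep_x: [60, 40, 20]   scale: True

comp  keep_x  nonzero  explained X var
   1      60       60          0.1869
   2      40       40          0.1475
   3      20       20          0.0360

training balanced error rate: 0.0000

        n  mean_position_cm1  shift_vs_reference_cm1
group
CTRL   10            1652.01                    0.00
MS     10            1656.00                    4.00
ALS    10            1656.01                    4.01
```

The recovered Amide I peak shift (+4 cm⁻¹ toward higher wavenumbers in both
disease-like groups) matches the injected α-helix shift; cross-validated
one-vs-rest AUROC on this cohort is 1.0 for every class
(`fs.cross_validated_values` + `fs.one_vs_rest_auroc`).

The full image-level pipeline is driven by a YAML config or the CLI:

```sh
fibrospec run-all --seed 1 --outdir out/        # simulate -> ... -> classify
fibrospec simulate --outdir sim/                # just the synthetic images
```

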