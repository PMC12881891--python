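# Methods

## Scope and model

`radiorbe` implements the analysis chain of a comparative radiobiology
experiment in which tumour cell lines (glioblastoma T98G, osteosarcoma U2-OS
and Saos-2) are exposed to photons (XRT), protons (PRT) or carbon ions (CIRT)
at 2, 4 and 6 Gy, both as 2D monolayers and as 3D spheroids.

### 2D: linear-quadratic clonogenic survival

Clonogenic survival after an acute dose *D* (Gy) follows the
linear-quadratic (LQ) model

    SF(D) = exp(−αD − βD²),   α ≥ 0 (Gy⁻¹), β ≥ 0 (Gy⁻²).

Derived summaries: D10 (positive root of βD² + αD + ln 0.1 = 0), SF2
(= SF(2)), the α/β ratio (Gy), and the iso-effect RBE — the ratio of
reference to test dose at equal survival, by convention the 10% level.
Survival is kept as a fraction in (0, 1] internally; percent is applied only
at report time.

Numerical choices:

* D10 and general iso-effect doses use the conjugate quadratic root
  `−2 ln S / (α + √(α² − 4β ln S))`, which is stable as β → 0; below
  β = 1e−12 the purely linear form `−ln S / α` is used.
* α/β is reported as undefined (`None` / empty cell) when β = 0, never as an
  infinity sentinel. Fitted coefficients pinned at the non-negativity bound
  are snapped to exactly 0 so that flag fires deterministically.
* A no-kill curve (α = β = 0) is legal; iso-effect queries on it raise an
  unattainable-effect error naming the curve.

Two reconstruction routes recover (α, β) from printed summary pairs, both
exact closed forms under α = rβ:

* from (D10, r):  β = ln 10 / (D10 (r + D10));
* from (SF2, r):  β = −ln SF2 / (2r + 4).

A two-point variant solves SF at two doses exactly and rejects pairs that
imply a negative coefficient.

### Clonogenic pipeline and its error model

Plating efficiency (PE) is the mean replicate colony count over cells
seeded; the surviving fraction is treated PE over the 0 Gy control PE of the
same cell line and modality. SF at dose 0 is exactly 1 by construction, so
the log-scale model has no intercept. Doses at which every replicate yields
zero colonies have undefined log survival; they are excluded from the fit
and flagged rather than imputed.

The LQ fit is a bounded linear least squares of −ln SF on (D, D²) with
α, β ≥ 0 (`scipy.optimize.lsq_linear`). Four error models are available:

* **gls** (default): generalised least squares under the Poisson counting
  model. Because every dose shares one control, log survivals are
  correlated: Cov(ln SF_i, ln SF_j) = δ_ij/T_i + 1/T_c, with T the summed
  colony counts of the dose (T_i) and of the control (T_c). The full
  covariance is inverted exactly and the parameter covariance is
  (Xᵀ Σ⁻¹ X)⁻¹.
* **poisson**: the diagonal approximation of the same model.
* **delta**: weights 1/se² with se from the replicate-spread delta method.
* **unweighted**: OLS with residual-rescaled covariance.

GLS is the default because, in 200-run simulations at the published seeding
scale with triplicate counts, it is the only scheme whose nominal 95%
intervals are calibrated (≈96% empirical coverage for both α and β, with
negligible bias). Delta-method weights estimated from three replicates are
chi-square-noisy and under-cover (≈80% for α); the diagonal Poisson scheme
ignores the shared-control correlation and over-covers β. All schemes give
essentially the same point estimates; only the uncertainty differs.

Confidence intervals are normal-approximation intervals from the known-
variance covariance; near the α, β ≥ 0 bounds they are approximate.

### 3D: spheroid growth, inhibition and 3D RBE

Each spheroid contributes a diameter time series on a 0–120 h grid at 24 h
intervals, the baseline measured before irradiation. Two slope estimators
are provided because both are in common use: the endpoint rate
(Δdiameter/Δtime) and the OLS regression slope of diameter on time
(default). They coincide exactly on linear and on 2-point tracks. Slopes are
computed per spheroid first and then averaged per condition — not pooled
into one regression — so the across-spheroid SD is reported. Units are
fixed: diameters µm, time h, slopes µm/h, recorded in output metadata.

Growth inhibition of an irradiated group is 1 − (rate_irradiated /
rate_control); the control must be growing. Values above 1 mean net
shrinkage and are retained. Per-modality (dose, inhibition) points, plus the
(0, 0) anchor, form a piecewise-linear dose-effect curve. The 3D RBE at an
effect level is dose_reference / dose_test with both doses obtained by
inverse linear interpolation.

Policies where the procedure is genuinely underdetermined:

* **Non-monotone curves** (which real slope tables do produce, e.g. a 6 Gy
  photon slope less negative than the 4 Gy one) are flagged; inverse
  interpolation refuses them unless the caller opts into
  pooled-adjacent-violators monotonisation. Repair is never silent.
* **Effect level**: no single level is privileged; `rbe_3d_sweep` reports
  the ratio over a grid spanning the common attainable range (21 levels by
  default), and the pipeline emits that sweep. Published headline 3D-RBE
  values cannot be pinned to a stated level, so the sweep makes the choice
  transparent rather than asserting one number.
* **Extrapolation** beyond the measured dose range is off by default and
  always flagged in the result when enabled.

### Assay indices

All three indices are ratios to the unirradiated control and therefore
invariant under common rescaling of the readouts: MTT viability percent
(100 × mean treated OD570 / mean control OD570), the resazurin spheroid
health index ((OD570/OD600)/size, higher = healthier), and the transwell
invasion index (mean invaded cells per field over control). Uncertainty is
the delta-method SD of a ratio of independent means. Spheroid "size" for the
resazurin normalisation defaults to projected area (∝ diameter²), with
diameter and spherical volume selectable, since the appropriate proxy
depends on how deeply the reagent penetrates.

## Synthetic data generator

The generator stands in for the study's undisclosed raw measurements; its
defaults are the study's stated conditions, not tuning knobs.

* **Colony counts**: Poisson with mean n_seeded · PE · SF(dose), triplicate
  replicates, seeding numbers from the published per-dose plan (250–20 000
  cells depending on line, modality and dose), control PEs 0.37 / 0.35 /
  0.34 (T98G / U2-OS / Saos-2). An optional negative-binomial dispersion
  knob supports robustness studies; overdispersion in the real data is
  unknown, so Poisson is the default assumption.
* **Spheroid tracks**: linear trajectories baseline + slope·t on the
  0–120 h grid, 16 spheroids per condition. Baselines are Gaussian
  (mean 500 µm — the published image scale-bar magnitude — SD 20 µm);
  measurement noise is Gaussian, SD 5 µm (~1% of the baseline; the source
  does not state a measurement error). Condition slopes are the published
  per-dose values; control slopes are derived from the published 120 h
  diameter increments (30/28/46%) at the 500 µm baseline. No plateau term is
  modelled: the analysis object is the slope, not the trajectory shape.
* **Assay plates**: log-normal multiplicative noise (CV 5% by default)
  around true relative levels taken from the published viability and
  invasion tables; invasion counts are Poisson-rounded around ~100 cells
  per field (five fields per insert).

LQ preset parameters are reconstructed from the published summary pairs:
photons from (D10, α/β) where both are printed, otherwise (SF2, α/β);
protons from (SF2, α/β); carbon ions from SF2 together with the D10 implied
by the published carbon-vs-photon RBE, via the exact two-point solve. For
T98G the printed carbon SF2 and implied D10 are mutually inconsistent with
any β ≥ 0 after rounding; the preset falls back to the purely linear
high-LET limit α = ln 10 / D10, preserving the RBE-defining D10 (implied
SF2 0.18 vs printed 0.16). Where a source quotes only a 2–6 Gy slope range,
the 4 Gy preset is the midpoint.

What the generator does **not** emulate: inter-experiment (day-to-day)
variance components, plating-density effects on PE, dose-rate or LET
microdosimetric structure, non-linear spheroid growth phases, and spatial
heterogeneity within a plate. Passing recovery tests therefore demonstrates
that the pipeline is correct and calibrated under the stated noise models,
not that those models exhaust real-data variability.

## Problem sizes

Defaults mirror the study design: triplicate colony counts over six doses
per modality, 16 spheroids × 6 time points per condition, five or six
wells/fields per assay condition. The calibration study uses 200 simulated
experiments; the large-sample consistency check scales seeding 100-fold.
These sizes make the full test suite and the reproduction script run in
seconds to a few minutes on one CPU.

## Known limitations

* The LQ fit assumes single acute doses; no repair-kinetics, fractionation
  (BED/EQD2) or LET-dependent microdosimetric extensions.
* Confidence intervals are Wald-type; for curves with very few usable doses
  or coefficients at the bounds they are approximate.
* 3D RBE depends on the chosen effect level whenever the two dose-effect
  curves are not exact dose-scalings of each other; the sweep exposes, but
  cannot remove, that dependence.
* Diameters are consumed as measurements; image segmentation, histology
  quantification and mechanistic growth models are out of scope.
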