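# Methods

## The phenological index

A plant's PI is the weighted mean of its reproductive units' stage
weights. The default `StageScheme` has four classes (bud, open flower,
immature fruit, mature fruit) with weights 1–4; any number of classes
with strictly increasing weights is supported, since all formulas are
written over the scheme. PI is undefined for a plant with zero
reproductive units — such plants raise an error at the plant level and are
excluded from sheet means (never treated as PI = 0); a sheet with no
reproductive plants is dropped to an explicit rejects list.

The sheet-level PI is the **unweighted** arithmetic mean of the per-plant
PIs. A pooled alternative (one PI over the merged counts, which weights
plants by their unit numbers) is available via `sheet_pi(..., pooled=True)`
but is not the default; nothing in the scoring protocol suggests plants
should count in proportion to their size. PI is carried at full floating
precision; two-decimal values such as 3.31 are display formatting only.

## Climate covariates

* `winter_ppt_mm` — cumulative precipitation of December of the year
  *before* collection plus January and February of the collection year.
  This "previous winter" assignment is the only one consistent with both a
  D–J–F window and climate drawn from the collection year and the year
  before it.
* `spring_tmax_c` — arithmetic mean of the March, April and May monthly
  maximum temperatures of the collection year.

The module consumes a pre-extracted monthly CSV (`id,year,month,ppt_mm,
tmax_c`); raster/PRISM acquisition is deliberately out of scope so the
package has no network dependency. Missing months are never imputed: the
affected specimen is rejected with the offending (id, year, month) named.
Note one terminological trap in the herbarium-phenology literature: the
precipitation covariate is *winter* precipitation even where prose
shorthand calls the delayed response a "spring precipitation" effect.

## The pheno-climatic models

Both models are ordinary least squares on the analysis table
(`doy ~ [pi +] winter_ppt_mm + spring_tmax_c`, intercept included). The
base fit is delegated to `statsmodels.OLS`; everything layered on it is
computed here:

* **Sequential (Type I) SS** — terms enter in the `ModelSpec`'s order
  (stage term first in the stage-aware model); each term's SS is the drop
  in residual SS when it enters, obtained by refitting the nested chain.
  F ratios divide each term's mean square by the **full** model's error
  mean square, the fixed-model ANOVA convention, with p from F(1, n−p−1).
  Order is part of the model specification: permuting correlated terms
  reallocates SS but cannot change coefficients, SSE, R² or AICc (tested).
* **AICc** — k = p + 2 parameters (slopes + intercept + error variance),
  with the full Gaussian log-likelihood including its constants:
  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1). AICc conventions differ across
  software by additive constants; this choice matches the major
  commercial ANOVA packages, and only *differences* between models fitted
  to the same data are meaningful.
* **Variance partition** — SS(term)/SST per sequential term plus SSE/SST;
  sums to one by construction.
* **Cross-validation** — a seeded uniform permutation split into k
  near-equal folds (remainders one per fold; default k = 10). Per-fold
  R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² with ȳ the **held-out fold's own mean** by
  default; `baseline="train"` uses the training mean instead. The fold
  baseline is the stricter of the two defensible definitions and is the
  default; both are exposed because the choice genuinely matters for small
  folds and is rarely stated in applications.
* **Comparison** — ΔR², relative R² gain (R²_b/R²_a − 1), ΔAICc and the
  relative error-variance ratio (SSE_a/SSE_b − 1).

Degenerate inputs fail loudly: rank-deficient designs raise a collinearity
error naming the first linearly dependent column, n ≤ p + 1 and n < 2k are
rejected, and missing values in model columns are an error rather than
silently dropped.

## Forecasting

A fit containing the stage term can be evaluated at any target PI within
the scheme's bounds and any climate values: the prediction is the linear
predictor, its SE the mean-response standard error √(x'Σx) (a full
prediction interval adding the residual variance is an option, off by
default). Covariates outside the fitted min–max (closed interval) set an
`extrapolated` flag but do not block prediction; predicted DOY is not
wrapped at year boundaries. The peak-flowering default target is PI = 2.5;
onset has no canonical PI and is left to the user. The stage-duration
estimate is simply the PI coefficient (days per unit PI) times the
scheme's k − 1 transitions — 3 under the default scheme — with SE scaled
the same way.

## Synthetic data generator

The generator emulates a scoring campaign whose collection days obey the
stage-aware model exactly:

1. Per specimen, draw a collection year (uniform 1950–1999), winter
   precipitation from a Gamma distribution (mean 400 mm, SD 200 mm — a
   Mediterranean-winter rainfall scale) and spring T_max from a Normal
   (mean 17 °C, SD 4 °C).
2. Onset DOY = intercept + d·w_min + b_ppt·PPT + b_tmax·Tmax + ε with
   ε ~ N(0, residual_sd) (default 25 d). Default coefficients:
   intercept 179.2 d, d = 17.08 d per unit PI, b_ppt = 0.02 d/mm,
   b_tmax = −4.14 d/°C.
3. Collection offset u over the reproductive window [0, (k−1)·d] is drawn
   uniformly, or tilted linearly toward early (`pre_peak`) or late
   (`post_peak`) stages with a strength in [0, 1] — the three collector
   behaviours that make raw DOY a biased proxy for peak flowering. Latent
   PI = w_min + u/d and DOY = onset + u.
4. Plants per sheet ~ 1 + Poisson(1.67) (mean 2.67) and units per plant
   ~ 1 + Poisson(39) (mean 40). Counts fall on the two classes bracketing
   the latent PI: the split probability is Beta-distributed around the
   exact interpolation weight with concentration `count_dispersion`
   (default 200), then binomial. The expected weighted mean equals the
   latent PI at every dispersion; this kernel is a tractable stand-in,
   not an inference target — any count distribution with the right mean
   satisfies the PI model.
5. Monthly climate rows are emitted so the covariate windows reproduce
   the drawn values (Dec/Jan/Feb split 40/35/25 with February taking the
   float remainder exactly; March/May at ±2 °C around the mean with April
   balancing it).

One `numpy` Generator seeded by the single config seed drives every draw,
so outputs are byte-identical across runs.

Two deliberate couplings:

* The metadata CSV stores a real calendar date, so the pipeline's DOY is
  an integer — day-level quantisation adds up to ±0.5 d of noise. The
  truth record keeps the exact float DOY and the achieved sheet PI; exact
  (1e-6) coefficient identifiability is therefore a property of the
  truth-record table, while the CSV pipeline recovers coefficients to the
  tolerance rounding permits.
* At `count_dispersion = inf` counts are rounded deterministically and the
  collection day is re-coupled to the *achieved* sheet PI: in the
  noise-free regime stage and date are deterministically linked, which is
  what makes the generating coefficients exactly identifiable.

Under the defaults the generated DOY spread (SD ≈ 34 d, from the variance
budget of window + climate + residual terms) sits inside ±30% of the
~34.6 d spread typical of real montane-herb datasets; this envelope is
asserted in the tests.

What the generator does **not** emulate: spatial structure (coordinates
are placeholder grid positions uncoupled from climate), elevation
gradients, temporal trends in climate, heteroscedastic or non-Gaussian
residuals, multi-year specimens, or scorer error in classing units.
Passing recovery tests therefore show the estimator is correct under the
model's own assumptions — not that real herbarium data satisfy them.

## Problem sizes and numerical tolerances

Recovery experiments use n = 500 specimens × 200 replicates (residual SD
25 d), which makes each coefficient's 2-SE coverage a sharp ~95% binomial
check; the oracle-equivalence sweep uses 50 datasets of n ≤ 30 at 1e-8
relative tolerance; sequential-SS conservation is asserted at 1e-8
relative everywhere it is computed. Exact identities (PI worked examples,
noiseless fits) are asserted at 1e-6–1e-12 absolute.

## Known limitations

* One Cell Counter XML file is taken to represent one plant; the plugin
  has no plant-partition concept, so multi-plant sheets must be scored as
  several files (or counts-table rows) sharing a `sheet_id`.
* Mixed models, spatial autocorrelation and year-as-predictor trend models
  are out of scope; the framework is two fixed-effect OLS models.
* The PI-based duration estimate assumes progression is linear in PI over
  the whole reproductive phase; stages of unequal length would bias it.
* AICc values are comparable only within a dataset and this package's
  likelihood convention.
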