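# Methods

## Model

Species richness of a beetle group across discrete reserves is modelled by
the power-law species–area relationship (SAR), fitted in linearised form by
ordinary least squares:

    log₁₀ S = log₁₀ c + z · log₁₀ A + ε,   ε ~ N(0, σ²)

The Gaussian error on the log scale corresponds to multiplicative lognormal
noise on the count scale; it is the error structure implied by fitting OLS
to log-transformed counts, and the synthetic generator uses exactly this
structure.  No weighting or robust errors are applied: the estimator is the
plain OLS that is the de-facto standard in the SAR literature, with
classical inference (SEs from s²(XᵀX)⁻¹, two-sided Student-t p-values).

Assumptions worth keeping in mind: reserves are treated as independent
isolates (no spatial autocorrelation, no nestedness of faunas), richness
counts are taken at face value (no detection/effort correction), and the
log–log relationship is linear across the full four-decade area range.

## Transformations

All responses and predictors are log₁₀-transformed.  Two variables can be
exactly zero and receive log₁₀(x + 1) instead: coprophagous Scarabaeoidea
richness (one reserve holds no dung beetles) and minimum elevation (coastal
reserves start at 0 m).  Latitude is log-transformed like every other
predictor; with Italian latitudes (37.9–46.0°) this is a nearly linear
reparameterisation, which is why latitude coefficients look large (a
coefficient of −11.6 on log₁₀ latitude spans ≈ 1 log₁₀-richness unit over
the national gradient).  Longitude is carried for provenance but never
modelled.  Back-transformed predictions subtract the 1 again (floored at
zero) for plus-one groups.

## The packaged dataset and its quirks

The fixture tabulates 23 Italian reserves (0.17–1700 km², the full
latitudinal gradient, coastal to montane) with richness for six groups
compiled from published faunal surveys.  Missingness is explicit: "-" or an
empty cell means "never surveyed", which is distinct from a genuine zero.
Three deliberate faithfulness choices:

- **Hydradephaga n = 14.** The table prints 15 water-beetle counts, but the
  reference SAR parameters for this group are reproduced only when reserve
  9 (Burano, a coastal reserve with a single recorded species) is excluded
  — consistent with the stated sample size of 14 in the source analysis.
  The fixture keeps all 15 values as printed; the analysis defaults (and
  the pipeline's provenance block) exclude reserve 9 for this group, and
  the golden test scans every leave-one-out variant to confirm the
  exclusion is unique.
- **Reserve 8 has two elevation sets** (the carabid and water-beetle
  surveys sampled different points).  Both are stored; the loader's
  `elevation_set` switch selects one, and the pipeline uses the
  water-beetle set for Hydradephaga covariate models.
- **Internal inconsistencies are preserved, not repaired.**  One reserve's
  stated elevational range (1820 m) differs from max − min (1800 m);
  loading warns but does not fail.

## ANCOVA

Slope homogeneity and intercept differences are incremental F-tests between
nested pooled models: separate lines per group → common slope with separate
intercepts → a single line.  The headline comparison uses the five trophic
groups only; total Scarabaeoidea is excluded because its observations
duplicate the coprophagous and phytophagous counts and would be
double-counted.  The *c*-value ordering reported alongside the pairwise
tests ranks groups by their own SAR intercepts (the scale on which
species-per-unit-area values are quoted), with "~" marking pairs whose
intercept ANCOVA is not significant at α = 0.05.  Pairwise p-values are
unadjusted by default (a Holm option exists) — with ten pairs this is
anticonservative, which is why the raw p-values are always reported.

## AICc and model selection

All 2⁶ = 64 subsets of {log-area, log-latitude, transformed min/max/mean
elevation, log-range} are fitted on identical complete-case rows (a
requirement for AICc comparability) and ranked by ascending AICc with

    AICc = −2·logLik + 2k + 2k(k+1)/(n − k − 1),
    logLik = −(n/2)(ln 2π + ln(RSS/n) + 1),

where k counts coefficients *plus the residual variance* — the Gaussian-ML
convention used by R's MuMIn, and the one that reproduces the reference
df column (area-only model: df = 3).  Models with ΔAICc ≤ 2 are reported as
equally supported.  Numerical edge cases: a perfect fit (RSS = 0) gets a
−∞ AICc sentinel and ranks first; AICc ties break toward fewer predictors,
then lexicographic subset order; subsets whose AICc is undefined
(n ≤ k + 1) are dropped with a warning; exactly collinear subsets are
fitted by pseudo-inverse and flagged rather than crashing the search.
Area is not forced into candidates — it competes like any other predictor.
Mean and maximum elevation are kept in the default pool even though the
reference best-model table displays only minimum and range columns; on the
packaged data the best models are identical under the 4- and 6-predictor
pools.

Selection caveat: with several inert candidates, the AICc-best model
matches the generating predictor set only about half the time even at
large n (each spurious covariate enters with probability
≈ P(χ²₁ > 2) ≈ 0.16, independent of noise level).  Area itself is
essentially always retained.  Recovery experiments therefore score both
exact-set accuracy and the per-predictor questions that are actually
answerable.

## Extinction projection

Fraction lost = 1 − (1 − loss)^z; expected counts are s₀ times that, with
half-away-from-zero rounding when whole species are reported.  The
smallest loss producing one expected extinction is the closed-form inverse
loss* = 1 − (1 − 1/s₀)^(1/z).  Two exponent sources are supported and
always labelled: the SAR slope, and the area coefficient of the AICc-best
multiple model (which holds latitude/elevation influences fixed while area
shrinks).  They tell different stories — for Carabidae the SAR gives
z ≈ 0.21 but the multiple model gives z ≈ 0.34 — so reports carry both
rather than silently choosing.  Percentages in reports are given to the
nearest point; golden comparisons allow ±1 percentage point because the
reference roundings mix floor and nearest.

## Synthetic generator

`SyntheticConfig` defaults emulate the real system: 23 reserves, areas
log-uniform over 0.17–1700 km², latitudes uniform over 37.9–46.0°,
elevations from min ~ U(0, 1000 m) and range ~ log-U(1, 2000 m) with
max = min + range and mean at mid-range, noise SD 0.2 on log₁₀ richness
(matching the residual scatter of the observed fits, R² ≈ 0.4–0.5 at
z ≈ 0.15–0.35), and integer-rounded counts.  Rounding can be disabled for
exact-recovery tests (noiseless data then returns the generating
parameters to machine precision).  What the generator does *not* emulate:
spatial structure, covariate correlations found in real orography (e.g.
area–elevation dependence), shared species pools between nearby reserves,
and survey-effort heterogeneity.  Passing recovery tests therefore
validate the estimator and selection machinery, not the ecological realism
of any particular dataset.  Seeding: one master seed; replicate i uses
seed + i, so experiments reproduce regardless of execution order.

## Printed-precision tolerances

Golden tests compare recomputed statistics to the published tables at one
unit in the last printed digit rather than by exact re-rounding, because
the source tables contain three small internal inconsistencies that exact
rounding cannot reproduce: a slope of 0.2446 printed as 0.25 (double
rounding via 0.245), an AICc of 5.253 printed as 5.2, and an adjusted R²
of 0.5748 printed as 0.58.  One printed value is asserted against its
self-consistent recomputation instead: the phytophagous SAR R² appears as
0.44, but the same row's t-statistic (t²/(t²+16) = 0.41) and the same
model's adjusted R² (0.38) both force R² = 0.41.

## Problem sizes

The packaged analysis is small (n = 14–18 per group, 64 candidate models
per selection); the full test suite, including the 100-replicate
calibration run at n = 200 and the property-based checks, completes in
well under a minute on a single core.
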