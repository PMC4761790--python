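# Methods

## Exotherm detection

A supercooled leaf that nucleates ice releases latent heat, producing a
transient rise (exotherm) against the cooling ramp. The detector smooths
the trace with a centered 5 s moving average, then finds the first index
from which the smoothed series rises by at least 0.3 K within 60 s. The
onset is refined to the local minimum between that index and the
following peak; NT is the smoothed temperature at the onset, FP the
smoothed maximum from onset until the trace falls back below NT. Only
the first exotherm is reported (extracellular freezing); later rises are
logged at debug level. A trace with no qualifying rise is a valid
censored outcome (leaves can stay unfrozen at −19 °C), not an error.

The 0.3 K / 60 s / 5 s defaults are declared tuning constants, set for a
2 °C·h⁻¹ ramp at 1 Hz where the between-sample cooling is ≈ 0.00056 K:
a genuine exotherm rises hundreds of times faster than the baseline
falls, so detection is insensitive to these values over a wide range
(the suite checks that lowering the threshold never loses a detection,
and that detection is invariant to adding a constant to the trace).

Reading NT and FP from the *smoothed* series avoids the low bias that
single-sample noise minima (σ ≈ 0.05 K) would otherwise impose on NT.
The cost is a small flattening of the exotherm peak: on a noise-free
rise of (FP − NT) over 30 s the smoothed maximum sits ~0.08 K below the
injected FP. Recovery is therefore asserted to within one sample step
*along the exotherm rise*, (FP − NT)/rise-samples ≈ 0.15 K, the landmark
quantization of the signal itself; measured errors are ≤ 0.12 K even
with noise.

## Photoinactivation and LT50

`PhI = 1 − F_fT/F_max`, with `F_max` the maximum Fv/Fm across all leaves
of the species including controls. PhI is clamped to [0, 1]: noisy Fv/Fm
can slightly exceed `F_max`, and negative damage is not meaningful.

LT50 interpolates linearly between the bracket (T₁, PhI₁ < 0.5) and
(T₂, PhI₂ > 0.5), scanning from warm to cold and taking the first
crossing; an exact PhI = 0.5 at a tested temperature returns that
temperature. Species never reaching 50 % damage at −19 °C are censored
`below_range` and carry NA rather than an extrapolated value —
extrapolation beyond the coldest tested temperature has no empirical
support. Damage already above 50 % at −5 °C is censored `above_range`.

Interpolation uses treatment-level **mean** PhI by default (one LT50 per
species). A per-replicate mode pairs the r-th leaf at each temperature
into pseudo-curves to produce an LT50 replicate sample for two-sample
mechanism tests; since the true replicate structure of such assays is a
design choice, both modes are exposed (`lt50_mode` in `RunConfig`).

With the logistic damage model at slope k = 1.5 K⁻¹, exact bracketed
interpolation on the −5/−10/−15/−19 grid carries an intrinsic
discretization error of up to ~1 K for midpoints near the middle of a
grid interval (e.g. true midpoint −9 → interpolated −8.05). This is a
property of the estimator on a coarse grid, not noise; the recovery
criterion (median |error| < 1.5 K under Fv/Fm noise σ = 0.03) sits
above it deliberately.

## Mechanism classification

NT replicates are compared against LT50 at α = 0.05 (conventional
default). Two samples: Shapiro–Wilk on each plus Levene's test gate a
pooled-variance t-test, otherwise Mann–Whitney U. One LT50 value (the
default): one-sample t when NT passes normality, otherwise Wilcoxon
signed-rank. Degenerate cases are resolved explicitly: all differences
zero → p = 1 (FA); constant NT strictly away from the value → the
difference is exact, p = 0. "LT50 occurred before NT" is read on the
cooling axis: damage at a *warmer* temperature than nucleation (mean
LT50 > mean NT, significant) is freezing sensitivity. A `below_range`
censored LT50 is provably below every NT, so the species is FT with an
NA p-value. Unclassifiable species are excluded from plot proportions
rather than imputed; per-plot FT/FA/FS fractions are counts over present
classified species and sum to one exactly.

With n = 5 replicates the Wilcoxon path cannot reach p < 0.0625, so
nonparametric one-sample classifications at that size can only be FA;
this small-sample conservatism is inherent to the rank test.

## Community components

Gower distance `|xᵢ − xⱼ| / range` uses the **global** pool range (all
species carrying the trait), matching standard functional-diversity
software; per-plot ranges would break cross-plot comparability. Covers
are renormalized to Σp = 1 after the engineer exclusion and per-trait
missing-value drops — the CWM/Rao formulas presuppose relative
abundances, which also makes every output invariant to cover rescaling.
Species missing a trait are dropped per-trait, so FP and LT50 components
may use different effective pools. Rao is the full double sum
p·D·p (equal to 2 Σ_{i<j} pᵢpⱼdᵢⱼ); a monoculture scores 0; a pool with
a single distinct trait value scores 0 for every plot.

## Trend and contrast statistics

Altitudinal trends are ordinary least squares with the two-sided slope
p-value (a constant response is reported as a flat line with p = 1
rather than an undefined fit). No multiple-testing correction is applied
across the CWM/FD regressions by default; a Holm adjustment helper is
provided. Growth-form contrasts use Kruskal–Wallis with tie correction
and a hand-implemented rank-sum Nemenyi post hoc: q = |r̄ᵢ − r̄ⱼ| /
√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ)), referred to the
studentized range distribution with k groups and infinite df (validated
against q₀.₀₅,₃,∞ = 3.314). Note an intrinsic small-sample property:
with three groups of n = 8 the minimal adjacent-pair p is 0.061, so
adjacent groups cannot separate at α = 0.05 below n = 12 even when
ranks are maximally separated. The compact letter display uses the
standard insert-and-absorb sweep. Trait correlations default to `auto`:
Pearson when both variables pass Shapiro–Wilk at 0.05, Spearman
otherwise.

## Synthetic generator

The generator emulates the statistical structure of a Mediterranean
high-mountain freezing survey; its defaults are the study conditions.

* **Pool**: 42 species — 8 cushions, 8 graminoids, 23 forbs, 3 shrubs;
  mechanism archetypes ≈ 20 FT / 18 FA / 4 FS allocated within growth
  forms (all graminoids tolerant). NT truths are normal around
  growth-form means near −7 °C (SD 1.2 K, clipped to [−13.2, −5.3]);
  LT50 is NT minus a tolerant gap (mean 6.5 K for graminoids, 3.5–4 K
  elsewhere), NT ± 0.2 K for avoiders, NT + ~2 K for sensitives (clipped
  to [−18.4, −5.3] so damage stays on the test grid). This yields a
  species-mean LT50 near −8.8 °C with graminoids ~4–7 K hardier than the
  other forms. FP is NT + ~3.5 K capped at −0.7 °C.
* **Thermograms**: ramp 0 → −19 °C at 2 °C·h⁻¹, 1 Hz, then a 600 s hold;
  exotherm as a 30 s linear rise to FP followed by exponential
  relaxation (τ = 120 s) back to the ramp — the minimal shape carrying
  the two observable landmarks; Gaussian sensor noise σ = 0.05 K.
  Replicate leaves draw NT around the species truth (SD 0.8 K);
  replicate NT below −19 °C yields a censored trace.
* **Damage**: logistic PhI in temperature (slope k = 1.5 K⁻¹, midpoint
  at the true LT50) — a standard sigmoid dose–response stand-in; Fv/Fm
  = 0.8·(1 − PhI) + N(0, 0.03), clamped to [0, 1]; 5 replicates per
  target temperature plus 5 controls.
* **Traits**: LDMC is rank-coupled to LT50 via a Gaussian copula at
  Spearman −0.55 (latent Pearson 2·sin(πρ/6)); Hmax, SLA and seed mass
  are independent lognormals.
* **Community**: 38 plot altitudes uniform on 1940–2428 m; covers from
  Gaussian altitudinal niches whose optima rise as true LT50 falls
  (hardier species peak higher; coupling strength settable, 0 = neutral).
  Niche widths are wider for soft low-optimum species (60 m base +
  110 m × softness): their tails reach the summit while narrow hardy
  specialists drop out downslope, so high plots mix hardy and soft
  species — the cover-weighted mean LT50 *declines* and Rao FD *rises*
  with altitude, and a niche model (rather than random log-normal
  covers) keeps both trends controllable and sign-testable. An engineer
  species occurs in every plot at 50–80 % cover; every plot keeps at
  least two accompanying species. Plot richness runs ~24–42 species.

What the generator does **not** emulate: spatial autocorrelation among
plots, interannual weather, phylogenetic structure, observation error in
cover estimates, within-species trait variation along the gradient, and
drought–freezing trait integration beyond the single LDMC coupling.
Passing tests therefore demonstrate that the estimators recover known
structure of this idealized data-generating process, not that field data
meet its assumptions.

## Problem sizes and numerical choices

The test suite and the acceptance script run the recovery simulations at
200 seeds (trend signs, LT50 recovery), 2000 replicates (null
calibration), 1000 random communities (Rao oracle) and one full-scale
study (42 species × 5 leaves ≈ 7.2 M thermogram samples, processed
per-leaf); the whole suite completes in well under a minute. Exact-oracle
comparisons use 1e−12; probabilistic checks use the binomial-SE bands
stated with each test. All randomness flows through
`numpy.random.default_rng` seeded per call; fixed seed ⇒ byte-identical
outputs, which the suite asserts.
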