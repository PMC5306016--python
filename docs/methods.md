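# Methods

This note documents the models and procedures implemented in
`mycomediate`, the assumptions behind them, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
establish about real survey data.

## Data model and cover conversion

Observations are plot × species × stratum records on the extended
Braun-Blanquet scale (r, +, 1, 2m, 2a, 2b, 3, 4, 5). Codes are converted
to the van der Maarel (1979) ordinal transform values 1–9 by default; the
table is configurable. Every downstream statistic is a ratio of converted
values or a rank statistic, so the analysis is invariant to any positive
rescaling of the table — what matters is only that the transform is
strictly increasing in the ordinal rank. Because these are ordinal
transforms rather than midpoint percentages, "abundances" are unitless
scores and back-transformed percentages can exceed 100%; relative
(share-type) metrics are unaffected.

Species recorded in both strata (tree juveniles in the herb layer) are
kept as separate (species, stratum) columns: the recorded stratum label,
not the species' life form, decides layer membership. Coordinates are
treated as planar metric (projected, metres); distances are Euclidean.

## Mycorrhizal weighting and community metrics

Mycorrhizal status maps to a weight: obligately AM → 1, never-AM → 0,
facultatively/mixed AM → w_mixed (default 0.5), unknown → excluded from
numerator *and* denominator (exclusion, not zeroing, is deliberate: an
unknown status is missing information, not evidence of absence).
Relative AM abundance is the weighted cover share, relative AM richness
the weighted presence share; both are reported as fractions internally
and percentages in reports. The log response ratio ln(herb total / woody
total) uses all recorded species including unknown-status ones, since it
measures stratum biomass structure, not mycorrhizal composition.

The strata comparison is a paired t test on per-plot differences — the
two strata are measured on the same plot, so the plot-matched design is
the natural choice (a Welch two-sample variant is available). A constant
nonzero difference with zero variance is reported as t = ±∞, p = 0
rather than an error.

## Ellenberg inference

Plot environment along an indicator axis is the cover-weighted mean of
the indicator values (1–9) of the species present, excluding species
flagged indifferent and species with missing values. No additional
machinery is layered on top: the weighted mean with exclusions is the
complete estimator. Both strata contribute by default (`herb_only`
switch available). The estimate is scale-invariant in the covers and
always lies inside the range of contributing values. Values outside
[1, 9] are rejected at read time. Where a measured soil pH exists, the
inferred soil-reaction value is validated by Pearson and Kendall
correlation over the paired plots.

## Statistical core

**Kendall τ-b.** Implemented from the pair-count definition with tie
corrections in both margins. Significance uses the tie-adjusted normal
approximation for the S statistic; for n ≤ 8 an exact permutation
enumeration replaces it. The O(n²) sign-matrix formulation is exact and
fast at survey sizes (hundreds of plots); a completely tied vector makes
τ undefined and raises.

**Segmented regression.** The mean function a + b₁x + b₂(x − ψ)₊ is
continuous at the breakpoint. SSE(ψ) is minimized over a dense grid
(200 points between the 5th and 95th percentile of x, at least 2 points
per side), computed in O(1) per candidate from suffix sums, then refined
by golden-section search between the best grid neighbours — deterministic
and testable, unlike iterative re-linearization. The breakpoint interval
is a case-bootstrap percentile CI (default 500 replicates, seeded).
Because ψ is selected to minimize SSE, a plain likelihood-ratio check for
"is there a breakpoint at all" is anticonservative; a breakpoint is
declared **material** only when the segmented model beats the single line
by more than 6 AIC units (the conventional strong-evidence margin,
Gaussian AIC with k = 5 vs 3). Under a global linear truth this margin
keeps the downstream restricted analysis honest; under the default
synthetic effect it is exceeded by a wide margin.

**Spatial GLS.** Errors follow cor(d) = (1 − nugget)·exp(−d/range) off
the diagonal, 1 on it. For fixed (range, nugget) the coefficients, scale
and likelihood have closed forms via a Cholesky solve; the two
correlation parameters are profiled by bounded L-BFGS-B on
(log range, logit nugget) with multi-start (default 5 seeded starts,
range starts at distance quantiles) to avoid local optima; proposals with
a non-PD correlation matrix are rejected inside the optimizer (a positive
nugget keeps duplicated coordinates PD). ML is the default so AIC is
comparable across fixed-effects structures; REML is available. AIC counts
k = p + 1 (+2 free correlation parameters). `correlation="none"` is exact
OLS, with the classical t reference distribution; GLS coefficient tests
use the normal approximation.

**AIC** is 2k − 2·loglik throughout.

## Path models

The five models relate woody AM relative abundance (x) and herb AM
relative abundance (y) with one covariate z each — inferred R, N, F, or
the log response ratio — plus a combined model with the best abiotic
covariate and the biotic one. The exact arrow diagram of the original
analyses is not recoverable, so the default structure is declared, not
asserted: the fully recursive DAG z→x, z→y, x→y (and its two-covariate
analogue), which makes "partial correlation analysis" literal — with
standardized variables the ML path coefficients are exactly the
standardized partial regression coefficients. Any recursive structure
can be supplied instead.

Fitting is Gaussian ML on standardized complete cases (listwise
deletion): each endogenous variable is regressed on its parents,
exogenous (co)variances are free, the implied covariance is
(I−B)⁻¹Ψ(I−B)⁻ᵀ, χ² = n·F_ML with df = p(p+1)/2 − k. The default
structures are saturated (χ² = 0, df = 0), so AIC ranking reduces to the
generalized variance of each model's variable set; the ranking is
deterministic with a model-id tie-break and refuses to compare fits on
different n. Note that the combined model spans four variables, whose
extra marginal likelihood dominates its AIC; it is reported primarily
for its path estimates. Spatial dependence is deliberately not modelled
inside the path stage.

The marginal residual test regresses the response on the covariates
(OLS), then tests the residuals against the predictor — slope t test on
the parametric branch, Kendall τ on the heteroscedasticity-robust branch.

## Pipeline

Stage order: metrics → strata tests → Ellenberg (+ pH validation) →
richness τ (full set, no spatial correction — a rank test over 400+
plots) → segmented fit → restricted-subset OLS and spatial GLS → path
models and marginal tests on the subset → sensitivity scan. The
sensitivity scan recomputes metrics for w_mixed = 0.00 … 1.00 (step
0.05, 21 rows), re-estimates the breakpoint per weight by default
(reusing the main ψ̂ is a config switch), and records failures in-row
without aborting the scan. No multiple-testing correction is applied by
default; a Benjamini–Hochberg column for the scan is available. A global
seed deterministically derives per-stage seeds; a re-run of `run_all` on
the same inputs is byte-identical.

## Synthetic data: what it emulates, and what it does not

The generator builds bundles shaped like a regional ancient-forest
survey: 415 plots in 77 forest clusters (plots scattered ~120 m around
forest centres in a 40 km region), 220 species (woody: 2 obligately AM,
22 facultative, 36 non-AM; herbaceous: 45/30/50 plus 35 of unknown
status — unknowns occur only among herbs), three environmental surfaces
(R, N, F analogues) with exponential spatial correlation (range 4 km,
nugget 0.2), Gaussian niche-driven species occurrence (niche sd 0.85,
optimum spread 2.0 on the 1–9 scale), lognormal covers discretized to
Braun-Blanquet codes, and measured pH for 126 plots as an affine function
of the R surface plus noise (sd 0.05). Covers that round below the
lowest class are treated as unrecorded — a detection limit, which keeps
the low end of the predictor from being floor-inflated.

The mediation mechanism: each plot draws an iid target p for its
weight-0.5 woody AM share from Beta(1.2, 14) (mass concentrated below
~15%, an explicit assumption), and the signal min(p, ψ*) with
ψ* = 0.043 drives (i) the obligate-AM herb cover share with slope
β_med = 1.6, (ii) AM herb occupancy (richness share) with slope
β_rich = 2.0, and (iii) the facultative-AM herb cover share *downward*
with slope 1.0·β_med (compositional replacement of facultative species
by obligate specialists as propagule supply rises). Effects (i) and (ii)
are separately tunable because abundance and richness responses are
distinct observables. The effect sizes follow from power calculations at
the survey size (below-breakpoint subset ≈ 150–200 plots, response noise
≈ 0.03–0.08 on the share scale → subset slope t ≈ 4, richness τ ≈ 0.14)
and were frozen as the default study conditions.

Two structural decisions matter for interpreting test results:

* **AM shares are plot-idiosyncratic.** The environment shapes which
  species occur (so Ellenberg inference has signal) but not the AM share
  itself. This makes predictor and response exactly independent when
  β_med = β_rich = 0, so the null-calibration tests check the test
  statistics, not an accident of the generator. Real communities likely
  violate this — environmental filtering of mycorrhizal types is one of
  the confounds the path models exist to address — so passing calibration
  here does not certify the richness τ as exactly nominal on real data.
* **The weight-0.5 share is the generating quantity, and obligate-AM
  woody species are nearly absent.** Recomputing metrics with extreme
  mixed weights therefore degrades the relationship from both ends: at
  w_mixed = 0 the predictor collapses onto two rare obligate species; at
  w_mixed = 1 the response is diluted by the facultative herb share whose
  signal component cancels. This reproduces the qualitative
  "significance fades at extreme weights" pattern, but the depth of the
  fade is a property of this mechanism, not a general theorem.

Also not emulated: phylogenetic trait structure, dispersal and
succession, observer error in code assignment, and any real taxonomy.

## Problem sizes and numerical settings used by the tests

The test suite runs the full-size study (415 plots) for calibration and
power (200 null + 100 effect replicates) and scaled-down bundles
(150–200 plots) for pipeline-level checks; breakpoint recovery uses
n = 400 with noise sd 0.05 and 200 bootstrap replicates per CI; GLS
recovery uses n = 300 with range 500 m and nugget 0.2 (100 replicates,
3 optimizer starts). Optimizer tolerances: 1e-8 (GLS profile), 1e-10
(golden-section on ψ). These sizes are the package's chosen test
conditions and are small enough to keep the whole suite in a few
minutes.

## Known limitations

* One breakpoint only; no Matérn/spherical correlation families; no
  variogram diagnostics.
* The percentile bootstrap for ψ is approximate near weakly identified
  breakpoints; the materiality flag (ΔAIC > 6) should be consulted
  before interpreting the interval.
* Path-model p values are classical OLS t approximations, adequate for
  the saturated recursive structures but not robust to non-normality.
* The exact permutation Kendall test is limited to n ≤ 8 by cost; the
  tie-adjusted normal approximation is used above that.
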