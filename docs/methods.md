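# Methods

`sizesel` analyses how temperature structures predator-prey body-size
relationships in stomach-content surveys of pelagic fish (the motivating
system is Southern Ocean lanternfish feeding on zooplankton along a
latitudinal sea-surface-temperature gradient, a space-for-time design).
This note describes the statistical machinery, the choices that were
genuinely open, and what the synthetic validation does and does not show.

## Response variables

For each fish with a non-empty stomach, the abundance-weighted mean prey
mass is the count-weighted arithmetic mean of the prey-taxon masses on the
linear gram scale, `Σ cᵢ mᵢ / Σ cᵢ`. The predator-prey mass ratio is

    PPMR = predator mass (g) / mean prey mass (g),

one value per stomach (prey-averaged PPMR), analysed as log₁₀ PPMR. The
linear-scale prey average is a deliberate choice: a geometric mean would
shift PPMR systematically downward whenever stomachs hold a size range, so
the two are not interchangeable; the linear mean matches the definition of
an "abundance-weighted average prey mass" in grams.

## Unit handling

Standard length (mm) converts to mass via the fisheries power law
`W = a·SLᵇ` with species-specific coefficients (packaged defaults
`a = 3·10⁻⁶ g·mm⁻ᵇ`, `b = 3.2` are typical of small mesopelagic fish; real
surveys supply their own). Zooplankton dry masses (mg) convert to wet mass
(g) with taxon conversion factors. Catch counts become densities in
individuals per 1000 m³ by dividing by the swept volume (distance towed ×
net mouth area, nominally 25 m²); note the division — it is the only
dimensionally coherent standardisation. Daily covariates (SST,
chlorophyll-a) are averaged over the 30 days up to and including the
sampling day; a gap in the window is an error, never silently
interpolated. Mass columns carry their units in the column name (`_g`);
downstream stages refuse undeclared mass columns.

Within a single haul all taxa share the tow geometry, so feeding-selection
weights are insensitive to whether abundances arrive per m² (Bongo nets)
or per 1000 m³ (midwater trawls) — the unit cancels in the normalisation.

## Prey-size selectivity

The core computation compares, on the log₁₀ prey-mass axis:

* the **realised** distribution — a Gaussian KDE of prey masses found in
  stomachs, weighted by item counts;
* the **environmental** distribution — a Gaussian KDE of zooplankton taxon
  masses, weighted by standardised abundance;
* their normalised ratio, the **preference** distribution, whose mean is
  the average preferred prey size. A flat preference means purely
  density-dependent (neutral) feeding.

Hauls are first grouped into sampling locations by single-linkage
clustering: two hauls join when within `max_km` great-circle kilometres
(default 100) *and* `max_days` days (default 5); groups are connected
components, with ids assigned by earliest date then southernmost latitude
so they are independent of row order. Within a location, predators of one
species are pooled into body-mass classes of width 10^0.05 g. Bins are
anchored at +0.025 on the log₁₀ axis (bounds at odd multiples of 0.025,
e.g. 10^-0.525 ≈ 0.30 g to 10^1.575 ≈ 37.58 g for the survey's size range),
half-open `[lower, upper)`; the anchor is configurable because other
surveys may phase their bins differently. Aggregates with fewer than
`min_prey` pooled prey items (default 10) cannot support a density
estimate and are dropped.

Numerical choices, all exposed in `SelectivityParams`:

* **Bandwidth** — Silverman's rule on the weighted sample, times
  `bandwidth_scale`. Count weights use the total item count as the
  effective sample size, making a weight of 2 behave exactly like a
  duplicated observation; abundance weights (arbitrary scale) use the Kish
  effective sample size. The KDE is evaluated directly as a weighted sum
  of Gaussian kernels because this dual weight semantics is not available
  in library KDEs. Validation requires results to be stable for bandwidth
  scale factors 0.75-1.5.
* **Grid** — 512 uniform points over the *comparable range*: the
  intersection of the realised and environmental log₁₀-mass ranges, padded
  outward by one environmental bandwidth. Both densities are renormalised
  to integrate to 1 over the grid (trapezoid rule).
* **Ratio stabilisation** — the environmental density is floored at the
  1st percentile of its positive grid values before division
  (`floor_quantile = 0.01`). Large prey are orders of magnitude rarer than
  small ones in these communities; an unfloored ratio explodes wherever
  availability vanishes at the range edge.
* **Mean preferred size** — the preference curve is treated as a
  probability density over log₁₀ mass and summarised by its expectation
  `∫ x·p(x) dx`. A degenerate sample (all prey one mass) degrades to a
  narrow Gaussian bump (bandwidth 0.05 log₁₀ g) rather than failing.
* The realised KDE weights prey records by their counts by default
  (`weight_by_count`), since a record of 5 copepods is five feeding
  events; a flag treats each record equally instead.

## Community diversity

Per-haul species densities (individuals per 1000 m³) are square-root
transformed — damping dominant species — before forming proportions, and
summarised by the Shannon-Wiener index `H = −Σ pᵢ ln pᵢ` (natural logs).
The transform is applied to densities, not proportions, and can be
disabled for sensitivity analysis. Diversity is computed per haul; if a
design needs station-aggregated compositions, aggregate before calling.

## Inference

Responses (all log₁₀: PPMR, predator mass, mean prey mass, preferred prey
size; plus diversity) are regressed on SST with linear mixed models: a
random intercept for sampling year and a random SST slope by predator
species. Fitting uses statsmodels `MixedLM`; because it supports a single
grouping factor, the crossed year-by-species structure is approximated by
grouping on species (`re_formula = 1 + sst`) and entering year as a
variance component within species — a standard workaround that is exact
when every species spans every year. Candidate fixed structures are
compared by ML-based AIC (final estimates refit with REML), ties broken
toward fewer parameters. Degenerate cases degrade loudly, never silently:
a single-level grouping factor or a numerically singular mixed fit falls
back to a fixed-effects fit with a logged note, and non-convergence is
flagged on the result.

Heteroscedastic residual structures (separate residual variances by year
and species, as `nlme`'s `varComb(varIdent(...))` would fit) have no
native equivalent in `MixedLM`; when requested, a two-stage feasible
weighting is applied — fit, estimate per-group residual SDs, refit on
variance-standardised data — and reported in the result notes as an
approximation. It is off by default.

Reported per model: coefficients with SEs, t and p under the containment
degrees-of-freedom approximation (n minus fixed coefficients; exact
software-specific df conventions are out of scope), AIC, and Nakagawa's
marginal/conditional R² from the variance decomposition (fixed, random,
residual). Effect sizes on the log₁₀-per-degree scale are translated to
percent change per °C as `100·(1 − 10^slope)` (positive = decline); a
slope of −0.053 is an ~11% decline per degree, −0.027 about 6%.

Residual spatial independence is checked with global Moran's I using
inverse great-circle-distance weights, zero diagonal, row-standardised
(the choice of weights is a convention; the test statistic, expectation
−1/(n−1) and randomisation-assumption normal approximation are standard).
Rows sharing a station are collapsed to their mean residual first so the
weight matrix stays finite. The implementation is validated against an
exhaustive brute-force double sum and holds its nominal size (rejection
rate 0.03-0.07 at α = 0.05) under permutation.

The diversity model is fitted by OLS with a Moran's I check rather than a
GLS with an explicit correlation structure; if residual autocorrelation
were detected, a spatial correlation term would be the next step.

## Synthetic validation

The generator is first-class, tested code: every downstream stage is
validated by recovering parameters it planted. Per station with 30-day
mean SST `T`:

* predator log₁₀ mass ~ Normal(median_s + (β_pred + b_s)·T + u_year, σ_mass),
  with species-level slope deviations `b_s` and year intercepts `u_year`;
* environmental prey log₁₀ mass ~ Normal(μ_env + β_env·T, σ_env),
  realised as a finite taxon list with right-skewed abundances, so the
  size-biased sampling oracle is an exact categorical distribution;
* stomach contents: Poisson item counts, each item drawn with replacement
  with probability ∝ abundance × exp(−(x − μ(m))²/2σ_k²), where
  μ(m) = selectivity_intercept + selectivity_slope·log₁₀(predator mass);
  σ_k = ∞ disables selection.

Default study conditions: 72 stations in 24 spatio-temporal clusters
(clusters a week or hundreds of km apart, so the co-occurrence clustering
must rediscover exactly 24 locations), SST 0-5 °C, ten species with log₁₀
mass medians −0.4…1.4 (matching the survey's 0.30-37.6 g size-class
range), 25 fish per station, mean 2.35 prey per stomach (≈ 3700 records
from ≈ 1600 stomachs), feeding kernel optimum −2.5 + 0.85·log₁₀(mass)
(the size-class coefficient scale observed in such data), kernel width
0.4, environmental pool lognormal around 1 mg (copepod-dominated) with
σ_env = 0.5. Species occupy Gaussian SST niches (width 1.2 °C, largest
species coldest): this community turnover is what concentrates each
station's catch into few species so that 10^0.05 g size classes
accumulate enough prey — and it reproduces the observed dominance of
small species in warm water. Within-species mass SD 0.1, year SD 0.05 and
species-slope SD 0.005 are set so grouping variance dominates residual
variance (conditional R² ≫ marginal, as in real stomach data); the
within-species variance is a free parameter because nothing in the design
pins it. Stations carry a 40-day daily SST series so the 30-day averaging
step is genuinely exercised; masses are generated from the realised
30-day mean, making the averaging stage part of the recovery loop.

Two scenario configurations recur in tests: the *hypothesis-1* scenario
(β_pred = −0.03, β_env = 0, selectivity slope 0, uniform species
sampling), under which mean prey mass is temperature-invariant and the
log₁₀ PPMR slope equals β_pred — note that with a size-tracking kernel
(slope > 0) the diet mean follows the shrinking predators and the PPMR
slope attenuates by roughly σ_e²/(σ_e²+σ_k²)·slope, which is why the
default conditions do not make this identity; and a *single-location
kernel-recovery* scenario (one species, one class, ~10⁴ prey draws) whose
preference mean must match both a binned frequency-ratio oracle (within
0.05 log₁₀ g) and the true kernel optimum (within 0.1).

What passing these tests shows: the estimators recover known structure
under the generator's assumptions (lognormal pools, Gaussian kernels,
linear temperature responses, correct grouping). What they do not show:
robustness to taxonomic aggregation error, gear selectivity, preservation
shrinkage, non-lognormal prey spectra, or diel/seasonal catchability —
none of which the generator emulates.

## Problem sizes

Validation runs use the default survey (~1800 fish, ~3500 prey records)
and 20-replicate recovery batches; these sizes give stable slope SEs
(~0.003 log₁₀ per °C) and sub-minute runtimes per batch, and scale
linearly for larger designs.

## Known limitations

* Crossed random effects are approximated (see above); studies needing
  exact crossed REML should export the stage CSVs to `lme4`/`nlme`.
* The preference mean is sensitive to the comparable-range definition
  when diets are censored at the range edge; the padded-intersection rule
  is one reasonable operationalisation, not the only one.
* Formal electivity indices (Ivlev, Chesson) and bootstrap confidence
  bands on preference curves are documented alternatives, not
  implemented.
* Depth stratification is not modelled; one haul per station per gear is
  assumed.
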