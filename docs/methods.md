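# Methods

This note documents the models and estimators implemented in
`habitatshift`, the conventions and defaults they use, and the design
choices made where more than one defensible option existed.

## Change accounting

A landscape at two dates is a pair of aligned categorical lattices over
one class legend; a cell contributes its fixed area (km²) to transition
entry (i, j) when it holds class *i* at the start date and class *j* at
the end. Cells that are nodata at *either* date are excluded, so the row
sums (start-date class areas) and column sums (end-date class areas) are
marginals of one common valid footprint and per-class net changes sum to
zero. No georeferencing is interpreted: grids must be pre-aligned, and
`cell_area` carries all spatial weighting. Per-class statistics follow
the usual land-change identities (net = gain − loss, gross = gain + loss,
annual = net/Δt, percents on the 0–100 scale, with percent change
reported missing — not zero — for a class with no start-date area).

The annualization divisor is an explicit parameter. The bundled Mexico
table reproduces its published annual column only with a divisor of 19
despite the 2000–2020 interval (e.g. built-up 10,790/19 ≈ 568); the
package defaults to `end_year − start_year` but the Mexico configuration
carries the published divisor and emits a warning whenever the two
disagree.

Zonal summaries recompute the transition matrix inside each zone of a
shape-identical zone lattice; by construction the zonal matrices sum
exactly to the extent matrix, which the tests assert. The per-zone
"percent gross change" counts each converted cell once
(100 · (1 − trace/total)).

## Resource distributions

Every land-cover class × season × resource carries a probability
distribution of resource value with closed-form moments stored alongside
the family parameters, so moment-based (expectation) and draw-based
(Monte Carlo) consumers are guaranteed consistent.

**Expert scores.** Responses on the 5-level rating scale
{0.10, 0.25, 0.5, 0.75, 0.95} are aggregated per class as a normal with
the across-respondent sample mean and n−1 SD (at least two respondents
required; off-scale scores are rejected at ingest). Scores are unitless
suitability indices in [0, 1], not densities.

**Legend crosswalk.** When scores were elicited on one classification
legend and areas are tabulated on another, an agreement matrix
(rows: target classes; entries: the fraction of the target class's area
composed of each source class, summing to 1) translates them. The default
rule is a weighted average of both the means and the SDs
(σ_target = Σ p_s σ_s). This is *not* the SD of the mixture; the
variance-correct pooling σ² = Σ p_s (σ_s² + μ_s²) − μ_target², which is
never smaller, is available as `sd_mode="pooled"`. The weighted-SD rule
is the default because it is the convention the bundled score tables were
built with; the package exposes both so their effect can be compared.

**Crop weighting.** A single cropland class takes the share-weighted
average of per-crop-type values, with shares renormalized after excluding
unattributable categories (e.g. grass/sod), so the class value reflects
the dominant crops actually grown in the extent.

**Milkweed density fitting.** Plot densities (plants/ha, ≥ 0, typically
60–91% zeros per class) are fitted by maximum likelihood to a candidate
set — exponential (on the raw values), negative binomial
(NB2: variance μ + αμ²) and zero-inflated Poisson (on rounded counts),
and a presence-only zero-inflated Bernoulli — and the AIC-minimal family
wins, ties breaking toward fewer parameters. Two comparability rules
matter here: the presence-only candidate assigns zero probability to any
count above 1 and therefore scores −∞ log-likelihood on genuinely
quantitative data, competing only for presence-like samples; and the
exponential's continuous density is compared against discrete pmfs at the
same data, which is the pragmatic convention when the candidate set mixes
supports. ZIP and NB likelihoods are maximized by Nelder–Mead in
transformed (logit/log) space; the tests check the fitted optima against
dense parameter-grid searches and against an independent zero-inflated
Poisson MLE implementation. An all-zero class collapses to a point mass
at zero; fewer than 20 included samples flags the fit as sparse
(threshold configurable) so callers can defer to the special rules.

**Special rules.** Classes known to carry no resource are forced to a
point mass at zero. A data-sparse class flanked by two well-sampled
neighbours takes the neighbours' common family with each parameter at the
midpoint of the two fits; note the parameter-level midpoint generally
differs from the midpoint of the two means (only for location-scale
families do they coincide). If the neighbour fits disagree in family the
target falls back to a normal at the moment midpoint, flagged in its
notes.

**Sampling and truncation.** Draws are made from a caller-supplied
`numpy` Generator, bit-reproducible under a fixed seed. Normal score
draws are clipped to [0, 1] by default (`"clip"`); exact truncated-normal
sampling (`"reject"`) and raw draws (`"none"`) are selectable. Count
families have nonnegative support, so the policy only affects the normal
family.

## Monte Carlo propagation

Per replicate, one value per class is drawn and applied to the class
areas at both dates (`shared_across_years`, the default), so
replicate-to-replicate variation in the change isolates value uncertainty
applied to the area deltas; `independent_per_year` draws separately per
date and inflates the change variance by year-to-year value noise.
Density (plants/ha) values are multiplied by 100 ha/km²; scores are
summed as-is, so score totals are relative indices whose absolute level
is not interpretable — only their percent change is. The default is
5,000 replicates; SE = SD(replicates)/√n_reps.

**Percent-change conventions.** Two are computed and reported:

* per-replicate — `100·(T₁−T₀)/T₀` averaged over replicates; this is the
  natural convention when the value distributions are the fitted,
  nonnegative families, and is reported as `percent_change`;
* ratio of means — `100·mean(T₁−T₀)/mean(T₀)`, reported as
  `percent_change_of_totals` with a delta-method SE.

The distinction matters when distributions are *reconstructed from
published moments only*: a normal (or even a nonnegative gamma) matched
to a mean far smaller than its SD lets replicate start totals approach
zero, and the per-replicate ratio then acquires heavy tails and
systematic bias, while the ratio of means converges to the analytic
expectation `Σ_c a_c E[V_c]`. All published-moment reconstructions in the
pipeline and acceptance script therefore use the ratio-of-means value.
For the same reason those reconstructions draw densities from untruncated
normals: the families actually fitted to the field data already enforce
nonnegative support, and clipping a high-variance normal at zero would
inflate its mean well above the published one.

Zone-level estimates share the same per-replicate class draws across all
zones, so zonal changes sum to the extent change replicate by replicate.
Cross-region rescaling places one region's zone changes on another's
scale by z-scoring with the source region's mean/SD and de-standardizing
with the reference region's; it requires a non-degenerate source SD and
reproduces the reference moments exactly.

## Trend analysis

Within-season observations (spring = March–May, fall =
September–November) are reduced to a per-pixel median composite per year
(missing pixels propagate only if missing in every observation), the
composite to an extent median over valid in-mask pixels, and the
resulting yearly series is fitted by closed-form OLS of value on calendar
year — centered for numerical stability, slope unchanged — with the
two-sided p-value from the t distribution on n − 2 df. A residual-free
series returns SE 0 with a `degenerate` flag rather than dividing by
zero. At least 3 distinct years are required; duplicate years are
rejected. Significance thresholds are left to the caller. The tests pin
the fit to an independent OLS implementation at machine precision and
verify the ~5% type-I error of the t test under seeded null simulations.

## Synthetic data

Generators return data *and* the realized ground truth. Landscapes draw
start classes iid from mixing proportions and move each cell by one step
of a prescribed row-stochastic matrix; surveys snap truth-plus-noise to
the nearest admissible rating level; plot samples mix a point mass at
zero with Poisson or negative binomial counts; seasonal stacks place
within-season observations around a linear yearly truth; agreement
matrices are Dirichlet rows concentrated on a preferred source class.
Defaults mirror the study conditions: 30 survey respondents, 5-level
scores, per-class zero fractions in the 0.6–0.9 range, 25-year seasonal
series with ~11 within-season observations, 30-m cells (0.0009 km²).

Deliberate simplifications: cells are spatially independent (no
patchiness) and zones are contiguous column blocks — adequate because
every downstream statistic is area-based, so spatial arrangement cannot
affect anything tested; real rasters also carry misclassification error,
which the generator does not emulate. Passing tests therefore demonstrate
the estimators' correctness on their stated model, not robustness to
classification error in real land-cover products.

## Problem sizes and defaults

Bundled reconstructions run the full 5,000 replicates (the study's
setting; well under a second per configuration). Test simulations use
landscapes of 120×120–200×200 cells, 500–8,000 Monte Carlo replicates,
20-seed repetition for coverage checks, and 500-rep null simulations for
the t test — sizes chosen so the complete suite exercises every
stochastic claim while remaining a desk-scale run.

## Known limitations

* The accounting assumes pre-aligned grids; there is no reprojection or
  resampling, and misaligned inputs fail loudly rather than being fixed.
* Class value draws are independent across classes; covariance between
  class values (e.g. a common drought year depressing all classes) is not
  modelled, so change SEs omit that term.
* Published-moment reconstructions cannot recover the exact Monte Carlo
  means of the original fitted-distribution runs (the fitted families,
  truncation behaviour and draw structure are not recoverable from
  printed means/SDs); they reproduce the expectations, and stochastic
  agreement is asserted only at Monte Carlo error scale.
* Score totals are relative: only percent changes of score-based
  resources are meaningful, and cross-region comparison of score-based
  changes requires the z-score rescaling with its strong
  distribution-shape assumption.
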