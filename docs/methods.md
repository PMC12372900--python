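# Methods

This note documents the models, conventions, and numerical choices
behind `airburden`, and what the synthetic-data generator does and does
not emulate.

## Exposure model and grids

Exposure lives on a regular latitude-longitude grid (default cell size
0.25° × 0.3125°, the resolution of nested regional chemical-transport
simulations over North America). Cells are half-open boxes
`[edge_i, edge_{i+1})`, so boundary points have an unambiguous owner.
Cell areas use the exact spherical-zone formula
`R²·Δλ·(sin φ₂ − sin φ₁)` with R = 6371.0088 km.

Each pollutant carries one chronic-exposure metric: annual mean for
PM2.5, NO2, and the hazardous air pollutants (formaldehyde,
acetaldehyde, benzene), and the peak-season mean of the maximum daily
8-hour ozone (MDA8 O3). The constructor enforces the metric/pollutant
pairing.

A *scenario set* bundles a baseline simulation with named zero-out
sensitivity simulations (default stages: `upstream_midstream`,
`downstream`, `end_use`). The contribution of a stage is defined as
baseline minus its sensitivity field, the standard zero-out attribution.

## Concentration-response models

Three families, all evaluated as three deterministic curves (central,
lower, upper confidence bound) so that burden intervals follow from the
risk model's confidence bounds rather than Monte Carlo:

- **Log-linear**: `RR(C) = exp(β·max(0, C − c₀))`,
  `β = ln(RR_Δ)/Δ` computed per published increment (all shipped hazard
  ratios are "per 10 units"). Shipped parameters: NO2 non-accidental
  mortality in the 65+ population 1.046 (1.044–1.049) per 10 ppb
  (adjusted for PM2.5 co-exposure), NO2 asthma onset in ages 1–18
  1.26 (1.10–1.37) per 10 ppb, MDA8 O3 COPD mortality (all ages)
  1.06 (1.03–1.10) per 10 ppb, PM2.5 preterm birth 1.12 (1.06–1.19) per
  10 µg/m³. Counterfactuals: 2.5 µg/m³ PM2.5, 2 ppb NO2, 32.4 ppb MDA8
  O3; RR = 1 at and below them.
- **Tabulated piecewise curve**: ordered (C, RR) nodes, linear
  interpolation in RR, RR = 1 at/below the first node, constant above
  the last (saturation). Used for supralinear PM2.5-mortality
  functions that are published as curves. The shipped default curve is
  **synthetic**: a concave stand-in spanning 2.5–83 µg/m³ with a mild
  slope (~1.08 per 10 µg/m³ near ambient levels) and ±15% bound
  spread; production assessments should load a published curve's nodes
  via the YAML registry. `build_hybrid_curve` splices a low-range and a
  high-range curve at a junction, rescaling the high curve
  multiplicatively to enforce continuity there — a declared convention,
  since published hybrids do not state their splice rule.
- **Unit risks**: lifetime excess cancer probability per 1 µg/m³
  (formaldehyde 11, acetaldehyde 2.2, benzene 7.8 per million). No
  counterfactual; risks are additive across pollutants. Lifetime
  incidences are annualized over a 76.4-year statistical lifespan.

The attributable fraction is `AF = (RR − 1)/RR`; for log-linear models
this equals `1 − exp(−β·excess)` exactly, which the tests verify to
1e-12.

## Spatial apportionment

County demographics and baseline rates are bridged to the grid by sparse
area-overlap weights. Intersection areas are computed in lon/lat degrees
with a cos(latitude) correction at each intersection's centroid;
at county scale the error against a fine-rasterization oracle is below
0.5% and far below demographic noise. Two weight normalizations are
kept: the fraction of the county's (in-domain) area per cell, used to
push county counts onto the grid (counties partially outside the domain
are renormalized over their in-domain portion; fully outside counties
are logged with a warning), and the county's share of the county-covered
area within each cell, used to split gridded population among counties
sharing a cell. County baseline rates are attached **unchanged** to each
(county, cell) overlap pair — burden math operates on pairs, never on a
blended per-cell rate — and aggregation to county/state/national level
is plain summation.

## Burden, attribution, uncertainty

Per endpoint: `burden_pair = AF(RR(C_cell)) · rate_county/10⁵ ·
population_pair`, with the population base either persons in the
endpoint's age range (adults 25+, elderly 65+, children 1–18, all ages
for COPD; age bins partially overlapping a range contribute
proportionally to the overlap) or annual births for preterm birth.

Stage attribution subtracts the sensitivity scenario's burden from the
baseline's at every level. Central estimates subtract everywhere;
uncertainty intervals are formed at the reporting level (state,
national) by combining relative errors in quadrature:
`rel_side = √(rel_side(base)² + rel_side(sens)²)`, each side's relative
half-width treated separately so asymmetric intervals stay asymmetric.
The single "combined relative uncertainty" quoted alongside an interval
uses each input's average half-width (symmetric convention); both
conventions reproduce the standard worked example (1800 with interval
1600–2000 from 14,800 (13,700–16,000) and 13,000 (11,900–14,100), 11%
combined) after nearest-100 rounding. Values are rounded only for
reporting (granularity configurable; nearest 100 for attributed-stage
intervals, matching common reporting practice) — raw values are always
retained. Zero-central values with zero width are treated as exact
zeros; zero centrals with nonzero width are rejected with guidance to
report absolute half-widths.

Mortality is computed per pollutant separately; overlap
(double/triple-counting of COPD deaths across PM2.5/NO2/O3) is **not**
subtracted, mirroring standard practice; the pollutant share table is a
diagnostic of it.

Additional operations: a uniform bias offset (`max(0, C − offset)`
applied consistently to baseline and sensitivities, for propagating a
robust-regression intercept as a systematic-bias scenario — note that on
a concave risk curve this can *raise* attributed burdens while lowering
all-source burdens), and threshold-crossing population counts (persons
in cells moved below a risk threshold when a source's total contribution
is removed).

## Disparities

Subgroups: Hispanic plus non-Hispanic Asian (incl. Pacific Islander,
merged because health data lump them), Black, Native American, and
white; the ~3% multiracial remainder is excluded from subgroup tables
but retained in totals. Exposure disparity is the population-weighted
mean concentration of a stage's contribution field; burden disparity is
the stage-attributed burden computed with subgroup populations and
subgroup age-standardized rates, divided by the subgroup's national
population. Both are normalized by the national total-population value
(relative disparity; the total population sits at 1 by construction).
Endpoints without subgroup-stratified incidence data (asthma, cancers)
use total-population rates, so their burden disparity pattern equals the
exposure pattern — documented behavior with a hook for stratified rates.

Suppressed county rates are resolved by a cascade: county-subgroup →
county-total → state-subgroup → state-total → national-subgroup →
national-total, recording which branch fired and how many entries were
filled. The bias sensitivity test scales every gap-filled rate by
±20% (and ±30%), recomputes relative disparities, and reports
per-subgroup shifts and whether the subgroup ranking changed — the
ranking stability is *verified on the data at hand*, never assumed.

## Model evaluation statistics

Sites must have ≥75% temporal coverage in every month of interest
(annual for PM2.5/NO2, March–August for ozone) to be retained.
Statistics: normalized mean bias `100·Σ(m−o)/Σo`; Pearson correlation
(labeled as such); standard major axis regression
(`slope = sign(r)·sd(y)/sd(x)`, symmetric in the axes); and the
Theil-Sen fit — median pairwise slope, intercept `median(y − slope·x)`,
with the distribution-free rank-based confidence interval
(scipy's joint-median implementation; the test suite checks it against
exhaustive pairwise enumeration for n ≤ 50).

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (arguments, seed):

- **Scenarios**: per-stage Gaussian-plume hotspots
  (`amp·exp(−d²/2ℓ²)`, default ℓ = 2 cells, amplitudes 0.5–4 scaled by
  each pollutant's background) on ambient backgrounds (PM2.5 6 µg/m³,
  NO2 4 ppb, MDA8 O3 40 ppb, formaldehyde 1.5, acetaldehyde 1.0,
  benzene 0.3 µg/m³ — chosen so backgrounds straddle the risk
  counterfactuals as real US fields do) plus Gaussian noise
  (σ = 0.2). The zero floor is applied to background+noise *before*
  adding the non-negative contributions, so
  `baseline − sensitivity == stored contribution` holds bit-exactly.
- **Population**: multinomial allocation of a requested national total
  over a smooth density surface, each subgroup with its own tilted
  surface (spatial segregation, hence non-trivial disparities); age
  structure from approximate US bin weights (0–1, 1–5, then 5-year bins
  to 85+). Births = half the 15–50 population × a configurable annual
  fertility rate (default 0.06) — the gridding of births is exposed as
  configuration because no single convention exists.
- **Counties**: axis-aligned rectangles with interior cuts jittered by
  up to half a cell, so county-cell overlaps are genuinely fractional;
  each row of counties forms a synthetic state.
- **Rates**: county×cause×subgroup truths around realistic magnitudes
  (non-accidental mortality ~700, COPD ~40, asthma onset ~190 per
  100,000/yr; preterm births ~10,000 per 100,000 births) with lognormal
  county variation and mild subgroup factors; annual event counts drawn
  Poisson(rate·population) and entries below the suppression threshold
  (default 10 events) suppressed — the same mechanism real vital-
  statistics databases use.
- **Observations**: daily per-site series equal to the model value at
  the site cell plus noise, with Bernoulli missingness and per-month
  completeness bookkeeping.

Not emulated: real geography, chemistry, or transport; demographic
correlation structure beyond smooth density tilts; within-year exposure
dynamics. Passing tests therefore demonstrate the *correctness of the
pipeline's arithmetic and invariances* (conservation, attribution
additivity for linear models, disparity invariances, determinism), not
the realism of any particular burden number.

## Numerical and design choices

- CI propagation by evaluating lower/central/upper curves
  deterministically — no Monte Carlo — matching how interval endpoints
  are reported in this literature.
- Rate denominators fixed at 100,000 person-years.
- Extrapolation above a tabulated curve's last node is constant.
- Degenerate inputs fail loudly: negative concentrations, RR < 1,
  suppressed rates reaching burden math, zero subgroup populations
  (flagged NaN with a warning, never silent zero), zero national values
  in disparity normalization.
- Default pipeline problem size (24×30 cells, 30 counties, 2M persons)
  keeps a full run under ~10 s while exercising every code path;
  all sizes scale via `RunConfig`.
- Text outputs are written with fixed float formatting and sorted keys;
  reruns under one seed are byte-identical.

## Known limitations

- The shipped PM2.5-mortality curve is a synthetic placeholder, not a
  published parameterization; results under it are structural, not
  citable burden estimates.
- No cessation lag, life-table years-of-life-lost, or within-year
  exposure dynamics; counts only.
- Differential exposure-response by race/ethnicity is not modeled
  (largely unquantified in the epidemiology); disparities arise from
  exposure, demographics, and baseline rates only.
- County polygons are simple polygons; multipolygon coastline complexity
  is out of scope.
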