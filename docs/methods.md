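# Methods

`alpscape` couples an agent-based model (ABM) of farm-level land-use change
with ensemble species distribution models (SDMs) to forecast how climate
and land-use scenarios jointly reshape plant species' potential ranges in a
topographically diverse Alpine region. Because the landscape, farm and
vegetation-plot data such a study rests on are licensed, the package ships
a synthetic-data module that emulates their statistical structure; every
downstream stage reads the same file formats (TIFF rasters with a JSON
geometry sidecar, CSV tables), so licensed data could be substituted
without code changes.

## Landscape and land use

The region is a pair of nested grids: land use at 25 m over 22 classes
(codes 1–22, each assigned to one of four habitat groups — agricultural
lands, grasslands, forests, alpine habitats), and elevation, calcareous
substrate, solar radiation and climate at 100 m, with every 100 m cell
covering exactly a 4×4 block of 25 m cells. The synthetic landscape builds
elevation as a monotone north–south ramp (valley floor 400 m, relief
1,500 m by default) plus smoothed Gaussian noise, and places habitat groups
by elevation band: agricultural classes on the lowest cells, alpine classes
on the highest cells above a 1,600 m treeline, grasslands and forests in
between. Within a band, classes are drawn from the configured mixture
weights, whose default is the region's current composition (67% forests,
19% grasslands, 9% agricultural lands, 6% alpine habitats at group level).

## Farm decision simulation

Farms (three types: cash crop, processing, livestock; intensity levels 1–5;
five farming styles) manage parcels — maximal same-class groups of 25 m
cells within one 100 m cell. Each simulated year runs through a fixed phase
order: economics → peer means → evaluation → action choice → action
application → rental-market clearing → market entry of released parcels →
succession.

- **Economics.** Income = Σ area × (gross margin + area subsidy); workload
  = Σ area × labour requirement, from an exogenous scenario timeline
  (BAU / SSP1 / SSP5). The shipped per-hectare values and scenario
  multiplier paths are illustrative defaults with the documented
  qualitative structure (SSP1 shifts subsidies toward low-input use, SSP5
  raises intensive margins and halves subsidies); they are not calibrated
  to farm accounting data.
- **Evaluation.** Workload is satisfactory at ≤ 1,800 hr/yr; income at
  > €20,000/yr *and* at least the mean income of same-type farms (self
  included, computed synchronously from the current year's economics; an
  exact tie with the peer mean counts as satisfied).
- **Decisions.** The joint evaluation state, farming type and style index a
  60-row probability table over ten actions (no change, intensify/extensify
  cropland or grassland, convert between cropland and grassland, adopt
  energy crops, expand, shrink-or-terminate). The default table is built
  programmatically from style archetypes (traditionalists inert, yield
  optimizers intensify/expand, idealists extensify, innovative farms adopt
  energy crops, support optimizers follow subsidy-rich activities) and can
  be replaced by any CSV with the same schema. Intensity and conversion
  actions apply to all eligible parcels in one year; shrink releases the
  single lowest-margin parcel, termination releases everything and
  deactivates the farm; actions illegal for a farm's holdings resolve to
  no-change so stochastic tables stay total.
- **Rental market.** Parcels already on the market are offered in seeded
  random order to expanding farms in seeded random order; a farm accepts
  until its projected workload reaches the 1,800 hr cap. Parcels released
  in year *t* join the market after year-*t* clearing, making them rentable
  exactly in years *t*+1..*t*+4.
- **Succession.** Fallow counters of market parcels increment at the end of
  every year (including the release year); at five uncultivated years the
  parcel retires irreversibly to scrub, and after a further 15 years
  (configurable) its cells become conifer or broad-leaved forest depending
  on parcel elevation (700 m split). Forests, alpine rock/grassland and the
  other static classes (ruderal, riparian, dry grassland, orchard, wetland)
  are never created from or converted to agriculture.

Replicates re-draw farming styles (uniform by default) and use independent
seeded substreams; national-park parcels belong to a passive owner and
never change. Scenario calendars are abstract years 0..N (N = 36 by
default, matching a mid-century horizon from a 2014 baseline).

## Representative runs

Each replicate's end-year map is summarized by Pielou evenness of class
area shares (single-class maps defined as 1) and the count of intensively
used 25 m cells (non-low-input cropland, ≥3-cut meadows, >1.5 LU/ha
pastures — all encoded in the class codes). After min–max normalizing both
axes (the indices have incommensurate units), the runs nearest the centroid
and the four corners of the bounding rectangle are selected; ties break to
the lower replicate id and duplicate winners fall to the next-nearest
unused run.

## Climate

Current monthly tmin/tmean/tmax/precipitation fields at 100 m are generated
with a 0.0055 °C/m lapse rate, a sinusoidal annual cycle (January coldest),
a spatially varying diurnal range on noise independent of elevation, and
precipitation whose seasonality and overall level vary on two further
independent smoothed fields — this construction keeps all pairwise
correlations among the four derived bioclim predictors below 0.75.
Future climate follows the anomaly chain: coarse monthly deltas
(forecast − hindcast; additive for temperature and, by default,
precipitation) are interpolated to 100 m with bicubic splines (bilinear
fallback with a warning below 4×4 support), added to the current fields,
precipitation floored at zero and the tmin ≤ tmean ≤ tmax ordering
re-asserted. The built-in scenario generator shifts the coldest-month
minimum temperature by +2.4/+3.0/+3.8 °C for RCP2.6/4.5/8.5. Coarse
precipitation can alternatively be downscaled by ordinary kriging with
elevation as external drift (exponential variogram with nugget fitted by
weighted least squares; exact at support points; degenerate residuals fall
back to the drift regression).

Bioclim definitions: BIO6 = minimum over months of tmin; BIO7 = maximum
tmax − BIO6; BIO15 = 100 × SD(monthly precipitation)/(1 + mean), the
ANUCLIM convention; BIO18 = precipitation of the warmest quarter, where
quarters are three consecutive calendar months, cyclic over the year
boundary, warmest by mean temperature with ties to the earliest window.

## Virtual species and plots

A species' suitability is the product of independent Gaussian responses to
the four bioclim variables, a land-use affinity vector over the 22 classes,
and a substrate factor (0.25 penalty on the wrong bedrock for sensitive
species); no interactions, so an analytic truth map is always available.
Suitability converts to presence probability through a steep logistic
(midpoint 0.40, slope 0.05, ceiling 0.95) — the usual virtual-species
device that keeps realized niches crisp enough for a distribution model to
recover while retaining probabilistic sampling. Planted specialists carry
≥90% of their affinity mass in one habitat group; climate-limited species
get narrow BIO6 breadths, land-use-limited species broad ones with
contrasting affinities. Niche optima are anchored to the generated
climate's actual BIO6 span (`pool_config_for_climate`): alpine specialists
sit at the cold edge (so that their warm-side decline is visible inside
today's alpine belt and any warming moves every cell away from the
optimum), agricultural and grassland specialists at or beyond the warm edge
(so warming moves the lowlands toward the optimum).

Plots are placed by blending area-proportional with uniform-by-class
allocation (50/50), the synthetic counterpart of targeted supplementary
sampling of rare land-use types; presence is Bernoulli per species and
plot. Species with fewer than 50 presences (configurable) are flagged for
exclusion, mirroring the minimum-occurrence filter such analyses apply.

## Ensemble SDMs

Per species, three classifiers are fitted on seven predictors (one-hot land
use, BIO6/7/15/18, substrate, solar): a random forest (200 trees, leaf size
2), a single-hidden-layer neural network (10 units, standardized inputs)
and a gradient boosting machine (100 trees, depth 3, learning rate 0.1) —
fixed, seedable settings standing in for the reference defaults of the
ecological modelling stack. Skill is the true skill statistic (TSS =
sensitivity + specificity − 1) at the threshold maximizing TSS, evaluated
on three stratified 80/20 splits and averaged; models under 0.5 are
excluded, survivors are refitted on all plots and weighted by mean TSS. The
reported ensemble TSS is itself evaluation-based (the weighted ensemble
scored on each held-out split). Projection builds a predictor vector per
25 m cell (climate, substrate and solar constant within the parent 100 m
cell), applies the TSS-weighted ensemble and binarizes at the threshold
that maximizes TSS on the fitting data — the same code path as plot-level
prediction. Permutation importance is 1 − Pearson r between predictions on
the original and the column-permuted table (land use permuted as one
categorical column, matching a single land-use importance score), averaged
over permutations and clipped to [0, 1].

## Range metrics

For species with a non-empty current range (C > 0; others are excluded and
logged): F and O are the future and overlapping suitable cell counts,
range-size ratio = F/C, exposure = (C − O)/C, log response ratio =
ln(F/C) with an empty future range floored at half a cell (flag recorded).
Habitat specialists are species with ≥75% (alternatively 50%/90%) of plot
occurrences in one habitat group; group responses average species'
run-mean log ratios. Richness change is the per-cell difference of stacked
binary maps. Run-level values aggregate as (mean, min, max) over the five
selected runs.

## Mixed models

The log response ratio is modelled by a Gaussian linear mixed model with
climate scenario × land-use scenario fixed effects (treatment coding,
current/current baseline), a species random intercept, and maximum
likelihood (not REML) so AIC is comparable across the four fixed-effect
variants (interaction, additive, climate omitted, land use omitted).
Exposure is a binomial GLMM with logit link: successes = displaced cells
C − O out of C trials, same structure, fitted by direct maximization of the
marginal likelihood with adaptive Gauss–Hermite quadrature (25 nodes
re-centred per species at the conditional mode); a small ridge (1e−6) keeps
estimates finite under complete separation; no frequentist binomial GLMM
exists in the installed Python stack, so this fitter is implemented here
and cross-checked against lme4's `glmer` in the test suite. Wald z tests
give p-values. R² follows Nakagawa–Schielzeth: Rm² = σ²_fixed/(σ²_fixed +
σ²_species + σ²_resid) with σ²_fixed the variance of the fixed-effect
linear predictor over the data, and σ²_resid = π²/3 on the logit scale;
Rc² adds σ²_species to the numerator.

## Problem sizes and numerical choices

The demonstration configuration runs a 120×120 25 m landscape (30×30 at
100 m), 60 farms, 50 species, 400 plots, 36 simulated years and 5 ABM
replicates over a {current, RCP8.5} × {current, BAU} scenario matrix; it
completes in a few minutes on one CPU and is bit-reproducible under a fixed
root seed (all randomness flows from named substreams of that seed; model
seeds are passed explicitly to every classifier). Structural experiments in
the test suite use 96–200 cell grids, 1,600–2,000 plots and up to 70
species. Ties in max-TSS thresholding resolve to the smallest achieving
threshold; single-class maps have evenness 1; kriging systems are
regularized with a small nugget if singular.

## What the synthetic data do and do not show

The generator reproduces the *structure* the analysis assumes — an
elevational climate gradient, class mixtures with realistic shares,
separable niches, specialist concentration, scenario-scale warming — but
not the measured values of any licensed data set. Passing tests therefore
demonstrate that the pipeline recovers planted signals (niches, specialist
identities, variance components, directional climate responses) and obeys
its conservation laws; they do not reproduce the source study's reported
coefficients, which derive from data this package cannot ship. Known
limitations: threshold-based binarization over-predicts small ranges (low
max-TSS thresholds for rare species), so truth-map recovery is asserted for
well-sampled species; the decision tables and economics are illustrative;
there is no dispersal limitation, livestock herd dynamics, labour market or
climate feedback on yields; parcels retain their last land-use class while
on the rental market; and the exposure GLMM weights by cell-count trials,
which inflates precision where ranges are large (a proportion-based
alternative is a documented caveat, not implemented).
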