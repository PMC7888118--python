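# Methods

## The problem

Animal telemetry yields presence-only data: a tag records where an animal
went, never where it did not. Fitting a presence/absence habitat model
(species distribution model) to such data requires simulated
"pseudo-absences", and the choice of generation method changes what the
model learns. `pseudoabs` implements the four standard generators and the
machinery to quantify their consequences: the environmental separation they
induce between presences and pseudo-absences, and the apparent explanatory
power and predictive skill of the habitat models fitted to them.

## Pseudo-absence generators

All four methods emit exactly one pseudo-absence per presence (1:1 ratio)
inside the study domain, each with a timestamp so time-indexed covariates
can be sampled consistently.

- **Background**: points uniform by area over the whole domain. For a
  lon/lat box, longitude is uniform and latitude is drawn uniform in
  sin(lat) (density proportional to cos lat); polygon domains use
  area-uniform rejection sampling. Each point inherits the timestamp of its
  index-matched presence — the method itself carries no movement
  information, and timestamp inheritance avoids introducing a temporal bias
  through the back door of dynamic-covariate extraction.
- **Buffer**: one point uniform by area on the geodesic disc of radius *r*
  around each presence (bearing uniform, distance = r·√u). The radius is
  the mode of the empirical step-length distribution. Draws landing outside
  the domain are retried up to 20 times; a presence whose disc has almost no
  in-domain area is skipped with a warning and its replacement drawn around
  a randomly chosen other presence, preserving the 1:1 count. No exclusion
  zone is imposed around the presence itself: the buffer formulation used
  here samples *within* a radius (availability), not outside one.
- **CRW / reverse CRW**: a correlated random walk that resamples paired
  (step length, turn angle) draws — always as pairs, never independently —
  from the empirical movement distribution. The forward walk starts at the
  track's first fix (the tagging location) with the track's initial
  bearing; the reverse walk starts at the last fix and assigns timestamps
  backwards to the tagging date, countering tag-deployment bias. The start
  fix is emitted as the first pseudo-absence so each animal's walk has
  exactly as many points as its track has fixes. Steps leaving the domain
  are redrawn up to 20 times, then the heading is reversed (reflected) and
  the turn redrawn — this keeps walks inside fenced or bounded domains
  without whole-track acceptance filtering. Whole-track selection on
  displacement or travel angle is noted in the literature as an option but
  is not applied here; the generator is a natural extension hook for it.

## Movement statistics

Tracks are regularized to a fixed interval by linear interpolation in time,
never extrapolating beyond the observed record, and split into segments at
gaps longer than `max_gap` (defaults mirror typical tag programmes: daily
fixes for oceanic animals, 6-hourly for terrestrial ones). Each interior
fix of a segment contributes one paired sample: the outgoing geodesic step
length and the signed bearing change from the incoming to the outgoing
displacement, wrapped to (−π, π], counterclockwise positive (a 90° right
turn is −π/2). The first fix of a segment has no incoming bearing and
contributes nothing.

The buffer radius is the histogram mode of the step lengths: equal-width
bins over [0, max step], ties broken toward the smaller bin, default bin
width 5% of the 95th-percentile step. A histogram mode is used because the
mode of a continuous sample is otherwise ill-defined; the default width is
coarse enough to be stable and fine enough to resolve the right-skewed
shape. Move distributions may be pooled across animals (the default) or
kept per animal; pooling is the default because per-animal samples from
short tracks are noisy.

All geodesy is spherical — haversine distances, initial bearings, and
destination points on the authalic Earth radius (6371.0072 km). One
convention serves both ~1 km terrestrial and ~100 km oceanic scales. A
consequence worth knowing: turn-angle negation under track reversal, exact
on the plane, holds only to O(step²/R²) on the sphere, and the
corresponding test uses a 5×10⁻³ rad tolerance.

## Synthetic worlds with known truth

The generator exists so that every downstream stage can be tested against a
known selection truth without restricted telemetry or remote-sensing data.
Environments are stacks of named layers on one lon/lat grid (cell-center
registered, row-major from the north-west corner): monotone **gradient**
ramps, **smoothed-noise** Gaussian random fields (white noise smoothed with
a Gaussian kernel whose sigma is the correlation length, rescaled so the
requested value range spans ±2 SD), and **distance-to-feature** fields (km
to the nearest of a point set, emulating distance-to-road/water predictors).
Layers are static or monthly (12 slices; monthly noise fields are
independent draws, monthly gradients get a sinusoidal seasonal offset). A
configurable fraction of cells is masked missing, emulating cloud cover.

Tracks follow a step-selection construction: at each step K candidate
destinations (default K = 15) are drawn from the movement model — paired
gamma step lengths (shape 2, right-skewed) and von Mises turn angles
concentrated at zero — and one candidate is chosen with probability
proportional to exp(Σ βⱼ zⱼ), where z are the candidate's covariates
standardized by domain-wide layer mean and SD. Standardization makes β
scale-free log-odds per SD. With β = 0 and K = 1 the walk is an unbiased
CRW, which is what the distribution-preservation tests exploit. Candidates
outside the domain or on missing cells are redrawn (cap 20); if no
candidate survives, the heading is resampled and, failing that, the animal
holds position for that step so timestamps stay regular. Per-animal
sub-seeds are spawned deterministically from the master seed.

What the generator deliberately does not emulate: positional (ARGOS) error,
behavioural state switching, tides/currents, and real remote-sensing
texture. Tests passing on these worlds therefore certify the pipeline's
statistical machinery and contracts, not the biological fidelity of any
particular real-data application.

### A scale effect worth knowing

How the methods order in environmental separation depends on movement scale
relative to the domain. When simulated steps are large or strongly
persistent relative to the domain, CRWs traverse the whole domain and
separate environments as much as background sampling does. The regime in
which background sampling induces the greatest separation and buffer the
least — the ordering reported for basin-scale oceanic tracking — is
diffusive movement over a large domain with presences confined to one side
(e.g. clustered tag deployments plus strong selection). The contrast-
ordering test constructs exactly that regime: 3 km mean steps, low angular
concentration (κ = 1), clustered starts, a ~500 km domain.

## Habitat-model families

All three families model label ∈ {0, 1} as a binomial response on the
covariates:

- **linear** (GLMM analogue): logistic regression with linear terms plus a
  per-animal intercept shrunk toward zero by a ridge penalty
  (`ridge_lambda`, default 1.0). The penalized group intercept is the
  random-effect contract — shrinkage toward the population mean — made
  explicit and testable; it is fitted by penalized IRLS.
- **smooth** (GAMM analogue): the same backbone with a cubic B-spline basis
  of dimension 5 per covariate (the "5 knots per variable" convention)
  replacing the linear terms. Prediction covariates are clipped to the
  training range before basis evaluation, since the basis is undefined
  beyond it.
- **trees** (BRT): stochastic gradient boosting with learning rate 0.005,
  bag fraction 0.75, interaction depth 5, and 2000 trees — the standard
  slow-learning recipe for telemetry SDMs. Seeded, hence reproducible. No
  random effect; tree ensembles absorb individual heterogeneity in the
  covariate space itself.

Predictions are always probabilities in [0, 1] and, for the mixed families,
population-level: the random intercept is set to zero at prediction time,
so models transfer to unseen animals. A dataset with a single animal drops
the random effect with a warning. Grid prediction emits one value per cell
and propagates missing predictors as missing cells (blank map pixels).

## Skill and separation metrics

- **AUC** is computed rank-based (Mann–Whitney with average ranks), i.e.
  the probability that a random presence outscores a random absence with
  ties counted ½; it matches exhaustive pair enumeration to 1e−12.
- **TSS** = max over thresholds of sensitivity + specificity − 1, with
  candidate thresholds at midpoints between consecutive unique scores plus
  sentinels beyond both extremes; the maximizing threshold is recorded.
  Maximization is used because no fixed threshold is standard for
  continuous habitat-suitability scores.
- **Explained deviance** (R²) = (null − residual)/null binomial deviance on
  training data, clipped at zero with a warning; for the trees family it is
  computed from the binomial deviance of training predictions against the
  intercept-only deviance.
- **Bhattacharyya coefficient** between presence and pseudo-absence samples
  of one covariate: Σᵢ √(p̂ᵢ q̂ᵢ) over 50 equal-width bins shared across the
  pooled range (1 = identical, 0 = disjoint). Fifty bins is a fixed,
  configurable default; with the ~2000-point samples used here it resolves
  distributional differences without starving bins.

Cross-validation schemes: **full** (train = test = all rows; the scheme
used for headline comparisons so that explanatory and predictive metrics
describe the same fit), **random75** (one seeded 75/25 split), and
**monthly** (leave-one-calendar-month-out, refusing datasets with fewer
than two months — a static world cannot support a temporal hold-out). Fold
metrics are aggregated by unweighted mean.

## The separation-skill analysis

For each model family, AUC is regressed (OLS) on the Bhattacharyya
coefficient, pooling points over the four methods and the top three
covariates; the slope's two-sided p-value tests whether environmental
separation drives apparent skill. "Top" covariates are ranked by the mean
trees-family feature importance across the per-method full-data fits —
importance needs a definition, and relative influence from the boosted
trees is the field's usual one. If the trees family is not requested, the
fallback ranking is the cross-method spread of BC per covariate. P-values
are reported unadjusted; the analysis fits one regression per family.
The regression pools methods and covariates within a family panel rather
than fitting per method, matching how the separation-skill relationship is
usually summarized.

## Benchmark problem sizes

The bundled benchmark study (used by `scripts/acceptance.py` and the
end-to-end tests) is an 80×80 grid at 0.1° with one east gradient under
selection (β = 3) and two smoothed-noise nuisance covariates, 10 animals ×
200 daily steps (~2,010 presences, ~4,000 model rows). At this size the
whole methods × families experiment runs in about a minute on one CPU with
the full 2000-tree boosted models. Direction-recovery properties are
asserted as majorities over 5–10 seeds rather than per-seed certainties,
since single seeds of a stochastic study can and do invert weak orderings.

## Numerical choices and edge cases

- IRLS: probabilities clipped to [1e−10, 1−1e−10]; convergence on relative
  deviance change < 1e−9, cap 100 iterations.
- Histogram-mode ties break toward the smaller bin; BC of two point masses
  at the same value is 1 by convention (zero pooled range).
- Containing-cell covariate lookup (no interpolation): keeps point/grid
  predictions exactly consistent and oracle tests exact; points on the
  grid's south/east outer edge belong to the last cell.
- Out-of-grid points extract NaN rather than raising; rows with any missing
  covariate are dropped from the model table with a per-label logged count,
  so the fitted label balance can deviate slightly from 1:1.
- Angle wrapping maps −π to +π so turn angles live in the half-open
  interval (−π, π].

## Known limitations

- The mixed families use ridge-shrunken group intercepts with a fixed
  penalty, not a variance component estimated by REML/ML; `ridge_lambda` is
  a tuning constant, and random slopes are not supported.
- Spherical (not ellipsoidal) geodesy; adequate at the ~0.1% level for the
  distances involved.
- The smooth family has no automatic smoothness selection; the basis
  dimension is the only knob.
- Buffer sampling treats the disc as available habitat regardless of
  barriers other than the domain boundary.
- No reprojection: all inputs are assumed lon/lat on the same grid.
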