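# Methods

This package implements an ensemble species-distribution-modelling (SDM)
pipeline with consensus forecasting, and a synthetic study system on which
every stage can be exercised and validated. This note describes the models
and procedures, the parameters that matter, the numerical choices, and what
the synthetic system does and does not establish about real data.

## The study system being emulated

The design mirrors a classic continental ensemble-forecasting study: a
gridded study area (8 km cells by default), seven climate variables — mean
annual temperature (MAT), mean warmest/coldest month temperature
(MWMT/MCMT), their difference (TD), degree-days above 5 °C (DD), and two
precipitation variables — plus elevation and optional soil layers; binary
presence grids per species; and a future-climate ensemble of 3 GCMs × 3
emissions scenarios × 3 thirty-year periods. Because no real rasters ship
with the package, a generator produces landscapes, virtual species, and
scenario sets with known ground truth.

### Synthetic landscapes

Each layer is a spatially autocorrelated Gaussian field: white noise
smoothed with a Gaussian kernel (`autocorr_range`, in cells) and
restandardized post hoc to the requested marginal mean and SD, so the
requested moments are exact over the grid. An optional deterministic
north–south trend per layer (`ns_gradient`, units per row) couples the
thermal layers the way real temperature surfaces are coupled; the default
layer set gives MAT ≈ N(8, 4) °C with a poleward cooling trend, DD ≈
N(2500, 700) degree-days, precipitation in mm. Smoothing is simple,
seedable, and requires no geostatistics dependency; it does not reproduce
anisotropy, elevational lapse structure, or heavy-tailed precipitation
fields.

### Virtual species

Suitability is a product of per-layer Gaussian kernels
exp(−(x − optimum)² / 2·breadth²), rescaled to a maximum of 1. Two
realization modes:

- **threshold** — occupy the top round(p·N) cells by suitability (seeded
  jitter breaks ties). Prevalence is hit exactly up to rounding. Because
  ranking is invariant to a common rescaling of all breadths, this mode
  cannot express absolute niche width; it is the right mode for
  position-controlled experiments (marginality recovery).
- **bernoulli** — scale suitability into occupancy probabilities
  min(c·suit, 1) with mean equal to the target prevalence (c found by
  bracketed bisection) and draw cells independently; redraw on a fresh
  substream if realized prevalence misses the target by >10 % relative,
  and fail explicitly when the landscape cannot support the target at
  all. Absolute breadth matters here; it is the right mode for
  width-controlled experiments (specialization recovery) and for
  model-fitting realism.

Virtual ranges are environmentally coherent but not spatially contiguous
the way polygon-derived rasterizations are; clumping artifacts of real
range maps are not emulated.

### Scenario sets

Future grids are the baseline plus additive per-layer offsets (optionally
with a row gradient) per (GCM, SRES, period). The default ensemble warms
by ~1–4 °C with emissions-rate × GCM-spread multipliers growing across
periods, winter temperatures rising faster than summer, and precipitation
moving a few percent either way — magnitudes in line with the CMIP3-era
scenario spread the 3 × 3 × 3 design mirrors. No downscaling or GCM
physics is modelled.

## Pseudo-absences and the split-sample

Presence-only data are converted to presence/absence by environmental
certification: the surface range envelope (SRE) spans the exact min–max of
every predictor over presence cells (an optional quantile trims the tails;
default 0/100 = extreme values), any cell inside the envelope is precluded,
and the remainder are true-absence candidates. 70 % of them are drawn
uniformly without replacement; presences plus drawn absences are split
7:3 into calibration/testing, stratified per class (calibration gets
floor(0.7·n) per stratum, remainder to testing, so the presence:absence
ratio matches between roles up to rounding). Three independent absence
draws crossed with three independent splits give nine bouts. The draw is
re-done per replicate; draws and splits are crossed, not nested. Child
seeds derive from the master seed by fixed arithmetic
(`SeedSequence([master, draw, split])`), so adding bouts never reshuffles
earlier ones.

## Model adapters

Eight adapter classes fill the roles of the classic niche-modelling
algorithm families, each backed by a scikit-learn learner (GLM → logistic
regression; GAM → cubic-spline logistic with a small basis, a few effective
degrees of freedom per predictor; MARS → degree-1 (hinge) spline logistic;
MDA → linear discriminant analysis; CTA → classification tree; GBM →
gradient-boosted trees; ANN → single-hidden-layer perceptron; RF → random
forest). An envelope adapter (probability exactly 1 inside the
calibration-presence envelope) is also available, and user classes can be
registered. Hyperparameters are fixed per class (no search). Fit failures
are first-class: recorded per (class, bout) key, visible in reports, and
excluded by the evaluation filter rather than crashing the run.

With the full design — 8 classes × 9 bouts — 72 models are calibrated per
species; projecting 9 scenarios gives 648 projections per future period,
plus 72 baseline projections.

## Evaluation and retention

AUC is the midrank Mann–Whitney statistic (P(score₊ > score₋) + ½·P(tie));
Cohen's kappa and TSS (sensitivity + specificity − 1) are computed from the
confusion table at the fixed 0.5 threshold. "Above 0.5" is read strictly: a
probability exactly at the threshold predicts absence (configurable). The
retention filter is the conjunction AUC ≥ 0.70 ∧ kappa ≥ 0.4 ∧ TSS ≥ 0.4 —
the stricter reading of an ambiguous AND/OR rule, and the conventional one.
Kappa is evaluated at 0.5, not at a maximizing threshold.

## Consensus combiners

All three combiners consume the same post-filter ensemble.

- **Average** — cellwise arithmetic mean.
- **Frequency** — fraction of projections predicting presence after
  binarization at 0.5; values lie on {0, 1/k, …, 1}.
- **Median (PCA)** — two steps. (1) Within each (bout, scenario) block,
  form the cells × model-classes matrix over masked-in cells, centre
  columns (no variance scaling — probabilities already share the [0, 1]
  scale), and take first principal-component scores. The PC1 sign is
  indeterminate, so the axis is oriented toward the ensemble majority:
  the sum of column correlations with it is made nonnegative. The
  projection with the largest **signed** correlation to the oriented axis
  is selected. Selecting on |corr| instead would let a projection exactly
  anti-correlated with the consensus win — the opposite of "represents the
  general trend" — so the oriented signed rule is used; with it, sign
  indeterminacy cannot affect selection and an anti-signal outlier never
  wins. Ties break by a fixed model-class order, never list position;
  all-constant blocks fall back to the first class with a warning.
  (2) Take the cellwise median of the selected projections (midpoint
  convention for even counts): 9 bouts × 9 scenarios = 81 for a future
  period, 9 at baseline (one per bout — the bout-level reading of the
  baseline selection).

Projection stacks are sorted by key before reduction so floating-point
sums are byte-identical however callers order their inputs. On outlier
robustness: replacing one of k projections by an adversarial constant
moves the median less than the mean *on average over cells* (the mean
shifts by |c − x|/k everywhere; the median moves only between adjacent
order statistics). The same dominance does **not** hold in sup-norm —
at a cell where adjacent order statistics are far apart the median jump
can exceed the mean's bounded shift — which is why the robustness tests
compare mean absolute movement.

## Range metrics

Maps binarize at strict 0.5. Area change is decomposed relative to the
current area: new = |future∧¬current|/|current|·100, lost =
|current∧¬future|/|current|·100, total = (|future|−|current|)/|current|·100,
so total = new − lost identically ("total change" is read as net change).
Centroids are probability-weighted mean centres of the cell-centre
coordinates. Distances use a local equirectangular approximation
(111.32 km per degree latitude; longitude scaled by cos(mean latitude)) —
adequate at the ~400 km extents simulated here; no geodesics. Shift is
reported as signed northward/eastward components plus a compass bearing
(from north, clockwise); identical centroids report bearing 0 with a
degeneracy flag.

## Congruence

The overlay classifies masked-in cells by how many of the three binary
consensus maps predict presence (good = 3, moderate = 2, poor = 1,
outside = 0); the consistency ratio is (moderate + poor)/good. Pairwise
similarity uses Pearson correlation on probability maps and Cohen's kappa
on binary maps, computed over the **full** masked-in grid (only the overlay
is restricted to union-of-presence cells); both domains are configurable.

## Niche traits

Six per-species traits: prevalence (fraction of presences in the
calibration data); latitudinal and elevation ranges (mean of the top
ceil(0.1·n) values minus mean of the bottom ceil(0.1·n) — ceiling
guarantees nonempty tails at small n); thermal range (the same 10 %-extreme
spread of presence-cell scores along the first axis of a PCA of the five
standardized thermal variables, with the two-axis cumulative variance
reported alongside; a 2-D Euclidean variant between tail centroids is
available behind a flag, since "a synthetic variable" spanning two axes is
ambiguous); and ENFA marginality and specialization.

ENFA: layers are z-scored over all masked-in cells. The marginality vector
m is the mean standardized environment at presences; global marginality
M = ‖m‖/1.96, so a species displaced ~2 global SD along one axis scores
≈ 1. Specialization is computed on the (p−1)-dimensional subspace
orthogonal to m: with species covariance Σ_S and global covariance Σ_G
projected onto that subspace, the generalized eigenvalues of
Σ_G v = λ Σ_S v are global-to-species variance ratios along the
specialization factors, and S = √(mean λ). A species sampling the
landscape uniformly has M ≈ 0 and S ≈ 1. Because published ENFA variants
differ in the exact eigen-decomposition, this construction is validated by
monotone-recovery properties on virtual species (Spearman ≥ 0.9 of M
against the planted optimum offset, and of S against inverse breadth)
rather than by matching another package's values to digits. One caveat the
recovery tests respect: when specialization is confined to a single
direction and marginality is ≈ 0, the orthogonal subspace is oriented by a
noise vector and can miss that direction, so width-controlled experiments
scale all niche breadths jointly.

## Trait regressions

Simple OLS and bidirectional stepwise selection (forward entry, backward
removal; classic entry/removal levels 0.05/0.10) relate mean pairwise map
correlation (and model accuracy) to nine candidate predictors: the six
traits plus mean AUC/kappa/TSS. The partial-F p-value of adding one
predictor equals the t-test p-value of its coefficient in the augmented
fit. Because each forward step screens several candidates at once, the
entry decision is Bonferroni-adjusted by default — the best candidate
enters if min(1, p·m) ≤ α_enter, where m is the number of candidates
screened — keeping the per-step false-entry rate near α_enter however many
noise predictors are offered (with 7 noise candidates and the raw rule, a
spurious third predictor would enter ~30 % of the time). `multiplicity="raw"`
restores the uncorrected rule. Removal uses raw p > α_remove. Selection is
deterministic; revisiting a previous model state terminates the loop.
Repeated-measures and two-way ANOVA summaries are delegated to standard
statistics routines in report scripts and are not part of the tested core.

## Pipeline, seeds, problem sizes

A single master seed spawns per-stage substreams via
`SeedSequence([master, crc32(stage), index])`; runs are byte-reproducible
end to end (the determinism test compares CSVs byte for byte). The shipped
analyses use a 50 × 50 landscape, 12-species cohorts, prevalence 0.15, and
one future period for the full 8-class design — sizes chosen so each
driver completes in seconds to minutes on one core while keeping ≥ 350
presences per species for stable trait estimation; trait-recovery
experiments use a 150 × 150 landscape so the diagonal marginality check
has ≥ 500 presences at prevalence 0.025.

## Known limitations

- Adapters are role-fillers with fixed hyperparameters, not
  reimplementations of the original algorithm families; absolute accuracy
  values are not comparable to published BIOMOD runs.
- Synthetic ranges lack rasterization clumping, dispersal limitation, and
  biotic structure; passing recovery tests shows the estimators recover
  *constructed* niche geometry, not that they are unbiased on real
  polygon-derived data.
- The equirectangular distance approximation degrades at continental
  extents and high latitudes.
- Raster I/O is plain-text ASCII grid / CSV; no projected CRS metadata is
  carried.
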