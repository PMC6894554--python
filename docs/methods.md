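# Methods

`denshab` implements a workflow for studying density-dependent habitat
selection in strongly territorial animals, using the grey-wolf
recolonization setting as its model system.  The central idea: for a
territorial species, what is *available* to a settling pack is not the whole
landscape but the part of it not already held by other packs.  As occupancy
rises, the available distribution of any habitat covariate shifts, so
apparent selection can strengthen, weaken, or switch sign even when
preferences are constant.  The pipeline therefore (1) reconstructs annual
territory mosaics and regional density surfaces from observations, (2)
re-defines each pack's availability domain each year, excluding occupied
space probabilistically, and (3) estimates a resource selection probability
function (RSPF) whose habitat coefficients interact with regional wolf
density.

## The model

The design table contains used points (drawn inside territory polygons,
coded 1) and unused points (drawn from the unoccupied availability domain,
coded 0).  Because the unused points are treated as genuine absences, a
binomial GLMM with logit link estimates a true probability of use:

    logit P(y = 1) = x'β + (x∘d)'γ + u_year + Σ_j b_{pack,j} x_j

* `x` — standardized habitat covariates; `d` — standardized regional wolf
  density; `x∘d` — covariate-by-density interactions (the habitat
  functional response: `γ_j ≠ 0` means the effective slope of covariate `j`
  changes with density, with sign switch at `d = −β_j/γ_j`).
* `u_year ~ N(0, σ_t²)` — iid year intercepts.
* `b_{pack,j} ~ N(0, σ_j²)` — independent per-pack coefficient deviations
  ("random slopes"), by default on every habitat covariate but not on
  density.  These absorb pack-level idiosyncrasy; without them, spatially
  autocorrelated but irrelevant covariates routinely reach spurious
  significance because territory-clustered points are pseudo-replicated.

All fixed effects are centred over the design table at fitting time, so
`z = 0` is the mean condition of the design and population-level summaries
are "conditional on mean wolf density".

### Estimation

Estimation is a deterministic Laplace approximation rather than MCMC or
nested integration: an inner penalized IRLS (Newton with step-halving)
finds the joint mode of all coefficients given the variances, and an outer
EM-type fixed point updates each variance from the posterior mean of its
block's squared deviations, `σ_j² ← (‖u_j‖² + tr Σ_jj)/q_j`.  The joint
design is sparse (one-hot random-effect columns), so each Newton step costs
O(n · k²) with k the per-row nonzeros, not O(n p²).  Fixed effects get a
wide Gaussian prior (sd 31.6, i.e. precision 0.001) purely for numerical
identification; with random-effect variances pinned at zero the fit
reproduces the ordinary logistic MLE to ~1e-6 relative at n = 5000.

Posterior summaries (mean, s.e., 2.5th/97.5th percentile, mode) come from
the Gaussian approximation at the mode, under which mode = mean; a distinct
mode column is reported for schema compatibility but cannot differ from the
mean here.  WAIC and a leave-one-out score (harmonic-mean conditional
predictive ordinate) are computed from seeded draws of the approximate
posterior; the harmonic-mean CPO is the crudest consistent estimator and is
reported as a mean log CPO for model comparison only.  Cross-checks against
`lme4::glmer` (Laplace) on shared data agree on fixed effects to ~0.02 and
on the year-intercept variance to well within its own uncertainty.

## Territory estimation

Annual territory boundaries follow a cascade keyed to data availability:
yearly fixed-kernel UD when a pack-year has ≥ 30 fixes; a 3-year moving
window when (t−1, t, t+1) pool to ≥ 30; otherwise the most recent kernel
estimate is carried forward (A), a pooled telemetry+track kernel estimate
is used (B), or the convex hull of track locations (C).  The territory is
the 95% volume isopleth — implemented as the smallest set of grid cells
(0.5 km default) whose cumulative mass reaches the level, polygonized, so
the contained mass is within one cell's mass of 0.95.  Kernel bandwidths
use a two-stage direct plug-in selector applied per axis (diagonal
bandwidth matrix), with the bivariate normal reference rule
`h_j = σ_j n^(−1/6)` as fallback for degenerate functionals.  Outlying
fixes are screened first: points farther from the coordinate-wise median
centre than median(d) + 6·MAD(d) are dropped, never more than 5% of a
pack's fixes.  No single screening rule is standard in home-range practice;
the MAD rule is this package's concrete, configurable choice.

## Density surfaces and occupancy uncertainty

The pack-by-year matrix holds observed sizes, 0 for absent, NaN for
not-surveyed.  Gaps flanked by detections on both sides are filled by the
midpoint (linear interpolation for multi-year gaps), rounded half-up;
a gap flanked by an absence resolves to absent.  Pack sizes become
territory densities, 1000·size/area (wolves per 1000 km²), burned into a
2-km raster; overlapping territories sum — summing is the one rule that
conserves total wolves.  The regional density surface is a
circular moving-window mean with radius equal to the median dispersal
distance, 55·ln 2 ≈ 38.12 km under the exponential dispersal model with
mean 55 km; edge cells average over the truncated window.

Boundary uncertainty: each pack-year polygon is rebuilt `n_sim` times with
its area drawn from a normal distribution — pack-specific sd about the
current-year area (method A) or long-term pack mean (B) when ≥ 2 telemetry
pack-years exist, population mean/sd otherwise — truncated below at 10% of
the mean.  Rescaling is by signed buffering with the offset solved by
Brent's method to 1% relative area; rescaling about the centroid would be
the main alternative — buffering preserves local boundary shape and is what
we chose.  The mean of the rasterized replicate
mosaics is P(cell occupied).  Replicates use per-pack substreams keyed by a
stable digest of the pack id, so adding a pack never perturbs another
pack's draws (common random numbers for monotonicity checks).

## Availability sampling

Each pack-year's availability domain is a disc of radius equal to the 0.95
dispersal quantile (−55·ln 0.05 ≈ 164.77 km < 165 km) about the territory
centroid, clipped to the study area, with the pack's own territory removed.
Used points: one per 50 km² of territory (minimum one) — about five for an
average 283 km² territory.  Unused points: one per 1000 km² of the domain,
of which a fraction equal to the year's measured territory-overlap
proportion is placed inside other occupied territories (territorial
tolerance rises with density); the remainder is a spatially balanced sample
— one jittered candidate per grid stratum, accepted with probability
1 − P(occupied) — so certainly-occupied space is excluded by the weight
itself and boundary cells enter in proportion to their uncertainty.

## The synthetic world

The generator supplies every statistical feature the analysis relies on,
with a known generative truth:

* **Landscape** — stationary Gaussian random fields by circulant embedding
  (exponential covariance, practical range 20–40 km, unit sill), five
  layers: three with true suitability weights (+1.0 prey, +0.6 cover,
  −0.8 human) and two pure-noise layers that exercise variable reduction
  and the signal-ranking checks.
* **Recolonization** — total abundance follows deterministic logistic
  growth (defaults N0 = 8, K = 240, r = 0.35 over 25 years, i.e. ~60 packs
  at the regional mean pack size of 4); sizes are integers ≥ 2 summing to
  the logistic total.  Settlement is ideal-preemptive: each new pack takes
  the highest-true-suitability admissible site, as a disc with area from
  Normal(283.10, 120) km² truncated at 10% of the mean.  A feedback
  controller admits settlement inside occupied space so the realized
  overlap proportion tracks a schedule that rises with abundance from 0
  toward 0.48 — matching a system where overlap grew from under 10% to
  about 48% as density saturated.  The schedule is only attainable while
  packs are still settling, which is why it is tied to abundance rather
  than to calendar year.
* **Telemetry** — weekly-scale fixes for a collared fraction of packs,
  drawn within the territory with density ∝ exp(0.5 · true suitability)
  times a Gaussian taper toward the centre, plus 150 m measurement noise
  (≥ 95% of fixes fall inside the true polygon).  The real within-territory
  distribution of wolf use is unknown; this choice simply gives recovery
  tests a defined truth.
* **Track surveys** — per-year detection (default 0.95), observed size =
  true size, designated panel-gap years recorded as not-surveyed.  Track
  points mix one quarter boundary points (marking/patrol) with
  interior points following the same tapered use distribution, so
  kernel (A/B) and hull (C) territory estimates see the same underlying
  use and agree in mean area within ~10%.

What the generator does **not** emulate: measurement error in pack counts,
within-year territory drift, lone-wolf space use, habitat change over time,
and autocorrelation between successive fixes.  Passing tests therefore
demonstrate that the estimators recover the truth of *this* data-generating
process at these sample sizes — not that any field dataset satisfies the
model's assumptions.

## Theory simulations

The four selection-ratio scenarios are 1-D Gaussian families whose means
and sds follow linear paths in occupancy; the paths are configuration, not
hard-coded theory, chosen to produce the four qualitative outcomes:
ratio *growth* at high covariate values when an important habitat is
limited (availability collapses faster than use), *flattening toward 1*
when important habitat is abundant, *weakening* when a limited habitat is
substitutable, and *constancy* when a substitute is abundant.  Densities
are kernel-estimated on a shared grid; ratios are reported only where the
available density exceeds 1e-8.

## Numerical choices and problem sizes

* Default raster: 2 km cells over 200×200 km; UD grids 0.5 km.
* Occupancy replicates: 100 for the file-writing analysis; 30 in the
  pipeline default and 6–8 in multi-seed validation experiments, where only
  the shape of the weight surface matters.
* Validation experiment sizes: parameter recovery at n = 20 000 × 20 seeds;
  end-to-end ranking over 10 worlds at default conditions; theory scenarios
  at 5 000 draws × 20 seeds.  These sizes give the binomial pass criteria
  (≥ 90%, ≥ 19/20) comfortable margins under the measured variability.
* Ties in the isopleth cell ordering are broken by array order; the
  one-cell mass tolerance makes this immaterial.
* Degenerate inputs fail loudly: coincident/collinear fixes raise
  bandwidth errors, constant covariates raise scaler errors, single-class
  tables are rejected, and complete separation flags the fit.

## Known limitations

* The Gaussian-approximate posterior cannot represent skew; percentile
  columns are symmetric by construction.
* The harmonic-mean CPO is high-variance; use WAIC for model comparison.
* Variance estimation by the Laplace/EM fixed point is slightly biased low
  for few levels (e.g. < 10 years), the usual Laplace behaviour.
* The availability disc is clipped to the study rectangle; in a real
  coastal or lake-bounded system the study mask should be supplied instead.
* `reduce_variables` pre-screens marginally; a covariate useful only in an
  interaction can be dropped before the hierarchical stage sees it.
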