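# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `exposeg`. It states how quantities are
computed; every empirical number it refers to is produced by the test suite,
the `analysis/` scripts, or `scripts/acceptance.py`.

## 1. Measurement pipeline

### Pings to individuals

Raw input is a table of device observations (`user_id`, epoch seconds,
WGS84 lat/lon, horizontal accuracy in metres). Processing:

1. **Accuracy filter.** Pings with reported accuracy worse than 100 m are
   dropped (a ping at exactly 100 m is kept — threshold sides are fixed
   choices, documented here once: accuracy ≤ 100 m; stationarity < 50 m;
   registry link ≤ 100 m; detection < D and < T strictly).
2. **Duplicate devices.** For each ordered user pair (u, v), u is removed
   when > 80% of u's pings match a ping of v exactly in (lat, lon, t).
   Mutual flags remove the user with fewer pings, then the
   lexicographically larger id. Comparison is a single pass, no cascading.
3. **Home inference.** Users need ≥ 500 pings (defaults; simulations use
   proportionally smaller floors). Each user's lat/lon is linearly
   interpolated onto hour boundaries (no extrapolation); hours in the local
   night window [18:00, 09:00) whose displacement to the next hour is below
   50 m are "stationary". A home requires stationary hours on ≥ 3 distinct
   local dates and ≥ 60% of them within 50 m of their medoid (the point
   minimizing total distance to the others); the home is the
   coordinate-wise median of the in-radius positions. For an even count,
   the median is the midpoint of the two central order statistics. All
   local times use a configured UTC offset; every failure carries a
   machine-readable reason.
4. **SES.** The home links to the nearest registry property (k-d tree in a
   local projection, exactness guaranteed by the refinement below); links
   beyond 100 m are dropped. SES is the property's monthly rent, upper-
   winsorized at $20,000. Two artifact filters follow: users with
   float-identical home coordinates are all removed (the identity precision
   is exact float equality — an interpretation, flagged as such), and users
   on a property shared by more than 10 linked users are removed.
   Alternative SES measures: average-rank percentile of rent scaled to
   [0, 100] (`(rank − 0.5)/n·100`, ties share the mean rank) and the
   synthetic block-group median income carried by the registry.

### Path-crossing detection

Two pings of distinct users form a qualifying pair when their great-circle
distance (haversine, sphere radius 6,371,008.8 m) is `< D` and their time
difference `< T` (defaults D = 50 m, T = 5 min; robustness variants are
plain configuration). An exposure event carries the minimum of the two
timestamps and the mean of the two coordinates. Consecutive qualifying
pairs of a dyad with inter-pair gaps `< T` collapse into one event
(attributes from the first pair, chain rule: each pair is compared to its
immediate predecessor). The collapse avoids counting one co-presence
episode once per ping; `collapse=False` preserves raw ping pairs, and the
raw event set — not the collapsed one — is superset-monotone in D and T
(merging episodes makes collapsed counts non-monotone; the suite tests
monotonicity on raw pairs deliberately).

The production detector buckets pings into windows of width T and runs k-d
tree radius queries on locally projected coordinates per bucket and
adjacent-bucket pair, with the query radius inflated 2% + 1 m over D to
cover equirectangular distortion (valid to ~100 km extents, mid-latitudes);
every candidate is then re-checked with the exact haversine/time predicate,
so the index changes speed, never results. Worst case O(n²) when all pings
share one place-time; O(n log n + candidates) otherwise. An exhaustive
all-pairs oracle with the identical predicate (capped at 50,000 pings) is
part of the public API and the acceptance suite proves exact equality on
100 random instances.

### Annotation

All rules act on the event's own point (the two-ping midpoint — an
interpretation; the alternative of annotating each contributing ping
separately is not implemented). Polygon containment is closed (boundary
points count as inside); overlapping polygons resolve to the smallest area.
Annotations: within 50 m of each endpoint's home; home-tract component
(both / one / neither endpoint inside their own home tract; events outside
all tracts count as "neither" and are logged); POI and hub membership (a
POI nested in a hub sets both ids); within 20 m of a road/rail polyline.
Hub coverage reports the share of events within 1 km of a hub next to the
land-area share within 1 km, the latter by exact polygon buffering and
intersection in the local projection (no Monte-Carlo approximation is
needed at these extents).

## 2. Estimating exposure segregation

Ego records restrict egos (not partners) to the region; partner lists are
deduplicated per ego (per stratum when decomposing — a documented choice;
the alternative of global dedup would leak cross-stratum information into
strata), and the ego never partners itself. `x` is standardized to mean 0,
variance 1 (ddof 0) over the egos entering the estimate, satisfying the
unit-variance assumption of the correction exactly in-sample; partner
values stay on the raw rent scale (the correlation is scale-invariant in
y, so y-standardization is omitted).

The naive estimator is the Pearson correlation of `x_i` with observed
partner means. The corrected estimator fits
`y_ij = a·x_i + b + ε⁽¹⁾_i + ε⁽²⁾_ij` by REML and reports
`a/√(a² + σ₁²)`. Implementation: with a group-constant covariate the
restricted likelihood depends on the data only through per-group
(n_i, Σy, Σy²); β and σ₂² are profiled out in closed form and the
criterion is minimized over λ = σ₁²/σ₂² ∈ [0, 10⁶] by bounded scalar
search on a log1p scale (tolerance 1e-8), with the λ = 0 boundary compared
explicitly against the interior optimum. A perfect fit floors the profiled
residual variance at 1e-300 to keep the criterion finite. The balanced
design reproduces the closed-form ANOVA estimators and the general case
matches `statsmodels.MixedLM` to ~1e-6 (both verified in the suite).

**Boundary pathology at the null.** When the true segregation is 0, both
a and σ₁² are 0; REML then estimates σ₁² = 0 with probability ≈ ½ and the
plug-in ratio returns sign(â) = ±1 — the estimand's 0/0 corner. The
estimator is kept exactly as defined (the fully degenerate fit a = 0,
σ₁² = 0 returns 0 with a note; fits at the boundary carry a note), and the
random-mixing endpoint is *measured* as the mean over 4,000 independent
replicate populations: the null distribution of the estimate is exactly
symmetric about 0 (flipping the sign of x flips the estimate), so the
replicate mean converges to the true value with standard error ≈ 0.012.
In real use this corner is immaterial — regional fits have σ₁² far from 0 —
but users estimating near-null populations should prefer the naive
estimator or replicate averaging.

The **NSI** is the correlation between SES and home-tract mean SES with the
ego included in the tract mean (census convention); the exposure measure
never includes the ego as a partner, so the two differ by O(1/tract size)
on the dense synthetic tract network — under 0.01 at the tract sizes used,
which is the nesting tolerance the acceptance suite asserts.
`synthetic_tract_network` draws partners uniformly without replacement
within tracts; with all co-residents it reproduces the NSI, with sparse
draws it reproduces it only after the mixed-model correction (the naive
estimate attenuates — the debiasing property).

Decompositions rebuild ego records per stratum: home-tract component, tie
strength (dyad event counts binned 1/2/3/4/5+ on the full network),
POI category, 3-hour local time window, and in-hub vs out-of-hub. Region-
level standardization of x is reused across strata (correlations are scale-
invariant, so this is presentational only). Strata failing estimator
preconditions are reported as not-estimable with a reason, never dropped.

## 3. The synthetic city

The generator emulates the measurement setting, not any particular city:

* **Geometry.** A flat rectangle in metric coordinates anchored at
  (38° N, 95° W); lat/lon via the inverse equirectangular projection.
  Tracts are a grid (default) or clipped Voronoi cells, 1 km scale.
* **Rents.** log-rent = μ + σ(√ρ·u_t + √(1−ρ)·z_i) with tract effects
  u_t ~ N(0,1): ρ (`tract_ses_autocorrelation`) is exactly the share of
  log-rent variance at the tract level. Defaults μ = 7.3, σ = 0.5 give a
  median rent ≈ $1,480/month with a realistic right tail. ρ = 1 collapses
  within-tract variance; ρ = 0 makes tract means indistinguishable (both
  are degenerate-limit tests).
* **Registry.** One property per home plus 15% vacant properties; CBGs are
  identified with tracts and carry income ≈ 40× the tract-level rent
  (rent-to-income ≈ 30% of monthly income).
* **Schedule.** Nights emit one candidate ping per whole local-clock hour
  in [18:00, 09:00), jittered within the hour, at the true home; days emit
  2 venue visits of 60 min with 3 pings each. `pings_per_day` thins the
  ~21 daily candidates by Bernoulli subsampling when set below the
  candidate count.
* **Venue choice.** Softmax over −d/ℓ − h·|z_v − z_i| with distance scale
  ℓ (default 1,500 m), homophily h ≥ 0, and venue target-SES z_v ~ N(0,1).
  This generative model is the package's own device for producing the
  documented sorting phenomena; its parameters are not calibrated to any
  published quantity.
* **Hubs.** 300 m squares holding 80% of POIs (round-robin). Placement:
  `embedded` at tract centroids (catchments SES-uniform under residential
  sorting), `bridging` at midpoints of shared boundaries between the most
  SES-dissimilar adjacent tracts, `random` uniform.
* **Noise and artifacts.** Reported accuracy is log-normal (median 15 m,
  log-sd 0.8, ~2% worse than 100 m — exercising the accuracy filter);
  positional noise is Gaussian with per-ping sd =
  `accuracy_noise_sd · accuracy/15`, so noise scales with reported accuracy
  and `accuracy_noise_sd = 0` disables it exactly. Duplicate devices
  (default 2%) clone a random 90% of a host's pings verbatim.
* **Ground truth.** True homes, rents, tract ids, venue target-SES, the
  duplicate map, noiseless per-ping positions, and the exhaustive true
  co-location event list (computed from noiseless positions with the same
  predicate and collapse semantics, by a separate windowed scan inside the
  generator). With noise off, detection must — and does — reproduce this
  list exactly.

All randomness flows from `config.seed` through named substreams; repeated
calls are byte-identical.

### What the generator does not emulate

No road-constrained movement or travel times; no within-venue positional
spread (visitors sit at the venue anchor, so co-location is exact); no
day-to-day routine persistence, household structure, workplaces, or
seasonality; duty-cycled ping gaps are modelled only through subsampling.
Passing tests therefore certify the *measurement machinery* (filters,
detection, estimation, indices) and the *directional mechanisms*, not
calibrated real-city magnitudes.

## 4. Simulation studies (fixed conditions)

Defined once in `exposeg.experiments` and shared by the tests, the analysis
scripts and the acceptance script:

* **Debiasing.** 200 replicates, 2,000 egos × 3 partners, true correlation
  0.5 (unit-variance latent means: slope ρ, σ₁² = 1 − ρ², σ₂² = 1): the
  naive estimand is ρ/√(1 + 1/3), bias ≈ −0.067, while the corrected
  estimator is unbiased within 0.02.
* **Endpoints.** Perfect segregation: 500 egos with distinct rents, 5
  partners each carrying the ego's own rent → corrected estimate 1. Random
  mixing: 2,000 egos × 5 i.i.d. partners, replicate-mean over 4,000
  populations → 0 (see the boundary note above). Bridging endpoints: 4 hubs
  × 25 homes, SES-uniform clusters → 0; identical-copy clusters → 1.
* **Mechanisms.** Homophily study: 250-person cities, embedded hubs,
  ρ = 0.6, default ℓ = 1.5 km (venue choice weakly local, so homophily is
  the dominant channel), h ∈ {0, 0.5, 1, 2} × 10 seeds; mean segregation
  must rise monotonically. Placement study: ℓ = 400 m, h = 0, ρ = 0.8, one
  hub per tract (catchment mixing is the only channel), 10 paired seeds;
  bridging placement must raise the bridging index and lower segregation.
  Mechanism studies report the naive estimator: these cities give each ego
  dozens of partners (attenuation negligible) and the corrected plug-in
  would inject boundary noise into a qualitative contrast.
* **Calibration.** Percentile-bootstrap 95% CI for a mean of 50 standard
  normals covers the truth 93–97% of 1,000 outer replicates (500 inner);
  Steiger's Z (shared-variable form, Fisher-z with the dependence
  correction) holds 4–6% type-I error at α = 0.05 under an equal-
  correlation null (n = 200, 5,000 simulations). Bootstrap p-values use
  (count + 1)/(B + 1), so they lie in (0, 1]; intervals are percentile
  (not BCa); no multiple-testing adjustment is applied anywhere. The
  bootstrap resamples egos within a region by default and whole regions
  for between-region contrasts, stated per analysis.

## 5. Other numerical choices

* Gini: population form via the sorted identity
  `G = 2Σᵢ i·x₍ᵢ₎/(nΣx) − (n+1)/n`; no small-sample correction (the
  bridging index is a ratio of like quantities). All-zero or negative
  input is an error.
* Nearest-hub distance uses hub polygon centroids (hubs are compact);
  distance ties break toward the smaller hub id. Splitting clusters can
  move the bridging index either way — refinement monotonicity is *not* a
  property and is deliberately not tested.
* Coordinates are written with 10 decimals (round-trip ≪ 1e-9°);
  timestamps are integer epoch seconds UTC; intervals are half-open
  [start, end) except where a rule is defined strict (< D, < T).
* Pipeline stages are resumable from their artifacts; a fixed config and
  seed reproduce reports byte-identically. The default-scale pipeline
  (2,000 individuals × 30 days ≈ 1.3M pings) runs in well under five
  minutes on one CPU; the committed study configuration (800 × 10 days)
  runs in seconds so the whole analysis sequence stays interactive.

## 6. Known limitations

* The corrected estimator's null-boundary instability (above) is inherent
  to the plug-in ratio, not to the implementation.
* Exact-float home-identity (filter 1) is a strict reading; real pipelines
  may want a small tolerance.
* The duplicate-device rule is single-pass; three-way clone chains could
  in principle leave one clone pair standing.
* The equirectangular index is not meant for continental extents; beyond
  ~100 km the radius inflation would need widening (the exact refinement
  keeps results correct regardless, at some speed cost).
* Venue-choice and schedule parameters are stylized; magnitudes of the
  mechanism effects are generator-specific even though their directions
  are robust across seeds.
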