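# Methods

This note documents the models and numerical choices behind each stage of
the pipeline, what the synthetic data emulate (and do not), and the design
decisions taken where the procedure left room.

## Movement preprocessing

Fixes carry bird id, UTC timestamp, lon/lat, altitude above sea level, fix
quality (2D/3D) and horizontal/vertical dilution of precision. Filters run
in a fixed order, and a ledger of removed counts always sums to input −
output:

1. **Quality** — keep 3D fixes with HDOP < 10 and VDOP < 10 (strict: a DOP
   of exactly 10 is removed).
2. **Interval** — greedy subsampling to 15 min: keep the first fix, then the
   earliest fix ≥ 14 min (target − 1 min tolerance) after the last kept
   fix. Data already at 15 min pass through unchanged.
3. **Daylight** — keep fixes with solar elevation ≥ −6° (civil twilight) at
   the fix position and time, from the standard NOAA ephemeris
   approximation (unrefracted; the −6° threshold dwarfs refraction).
   Latitudes poleward of 66.5° warn (twilight can be undefined) but apply
   the same rule.
4. **Independence** — for birds with a known natal nest, all fixes before
   the first great-circle excursion > 10 km are dropped; later returns are
   kept.
5. **AGL** — altitude above ground = telemetry ASL − bilinear DEM sample;
   keep AGL ∈ [−50, 4000] m, bounds inclusive (a 10⁻⁶ m epsilon absorbs
   projection round-trip noise at the exact boundary).

Tracks are planar: lon/lat convert through a local equirectangular
projection anchored at the raster origin. At a few-hundred-km desert extent
the distance distortion is far below GPS noise. Steps split into bursts
wherever the gap exceeds twice the nominal interval (30 min); per step we
compute speed V (displacement/Δt, km/h), the signed and absolute turning
angle θ between successive step headings, and persistence velocity
Vp = V·cos θ. The first step of a burst has no defined θ (it is carried as
0 and flagged); zero-length steps carry the previous heading, flagged.
"Speed" is necessarily step-average speed — only positions are observed.

## Behavioral change point analysis

Within a burst, Vp is modeled as a Gaussian process with mean μ, standard
deviation σ and autocorrelation ρ per nominal 15-min interval. Gaps enter
as real exponents: X_i | X_{i−1} ~ N(μ + ρ^{Δt_i}(X_{i−1} − μ),
σ²(1 − ρ^{2Δt_i})), the first point of a burst marginal N(μ, σ²). For fixed
ρ, μ and σ profile in closed form (weighted least squares on standardized
one-step residuals), so estimation reduces to a one-dimensional search:
`fit_msr` uses a bounded scalar optimization (the ρ = 0 endpoint, where the
likelihood is exactly the iid Gaussian one, is checked explicitly);
windowed fits evaluate a 21-point ρ grid (0 to 0.99) for speed, which is
ample for model and break selection.

Each 30-point window fits eight models — M0 (no change) through every
subset of {μ, σ, ρ} changing at a candidate break b, with at least 5 points
on each side — and selects by BIC = −2 logL + k ln 30, where k = 3 for M0
and 3 + |changed set| + 1 otherwise (the break location costs one
parameter). Models with parameters shared across the two regimes are fitted
jointly: shared-σ models pool residual sums of squares; shared-μ models
iterate the variance-weighted mean (4 iterations, well within tolerance at
window sizes used).

Windows advance by one step and never span bursts. Every non-M0 window
whose BIC improvement over M0 is at least 10 casts a vote for its break
index; votes within 4 indices agglomerate, and groups with ≥ 3 votes become
a changepoint at the group's lower median. The vote-strength floor and
support threshold were calibrated on the stated operating characteristics:
on stationary AR(1) series (n = 200, ρ = 0.3) the pipeline produces ≈ 0.04
false changepoints per series, while a 4σ mean shift is recovered within ±3
indices in 97 of 100 seeded series. Per-window false alarms grow with the
null's autocorrelation (M0 is selected in ~83% of white-noise windows but
only ~76% at ρ = 0.3 and ~61% at ρ = 0.6); the consolidation stage is what
controls the final false-positive rate. A diagnostic
(`window_sensitivity`) reports segment counts under alternative window
sizes.

## Segment features and state clustering

Segments are summarized by the median speed, median absolute turning angle,
and median AGL of their member steps. Segments with fewer than 5 points or
no defined turning angle are excluded: a median over one or two turns is
noise, and burst-edge slivers otherwise seed a phantom cluster.

Speed and AGL are strictly positive and span orders of magnitude between
the slow low-altitude and fast high-altitude states, so they enter
clustering on the log scale; turning angle stays linear; all three columns
are then z-scored. (A raw-space mode exists. In raw z-scores the
high-altitude tails compress the low-band speed contrast to ~0.3 z and the
clustering degrades badly — the log scale is also the one on which the
states' box plots are conventionally displayed.)

The number of states is chosen by an automated elbow: the k maximizing the
perpendicular distance from (k, log WSS_k) to the chord joining k = 1 and
k = k_max, with WSS the best of 25 seeded k-means restarts (non-monotone
curves are refit with more restarts, then clamped). The log scale makes the
criterion sensitive to the *last substantial multiplicative drop* — on a
linear scale the chord criterion systematically picks one cluster too few
when cluster sizes are unequal. Elbow *strength* is judged on the
axis-normalized curve: a single Gaussian blob peaks near 0.26 there while
genuinely clustered data exceed 0.45, so a maximum below 0.35 is flagged
"no strong elbow" and returns k = 1.

Clusters are renumbered deterministically from their raw-unit centers.
With four clusters the band structure is two low-AGL plus two high-AGL
states by definition, so the split is the middle of the AGL ordering;
within the low band the higher-median-turn cluster is state 1, and within
the high band the lower-AGL cluster is state 3. Other k fall back to
ordering by center AGL. (An adaptive largest-gap split was tried and
rejected: transition segments attenuate the high clusters' AGL centers
enough that the gap between the two high states can exceed the low/high
divide, silently flipping the low-band labels.) The per-bird/pooled comparison reports each bird's elbow choice
(birds under 30 segments excluded) next to the pooled one.

State contrasts use a Wilcoxon–Mann–Whitney z with tie correction and a
0.5 continuity correction toward the null; z > 0 means the first group is
stochastically larger. For samples of a few observations the normal
approximation deviates from the exact permutation p by up to ~0.1 in the
mid-range — fine for the enormous samples it is applied to here.

## Habitat-association models

For each fix (the unit of analysis; a per-segment mode exists because fixes
within a segment are serially dependent — the caveat is documented, not
silently resolved), the response contrasts behavioral bands: low (states
1–2) vs high (3–4), state 1 vs 2 within the low band, and state 3 vs 4
within the high band. Fixed-effect candidates are elevation, northness,
eastness, slope (each rescaled to mean 0, sd 0.5 by centering and dividing
by twice the sample standard deviation, so coefficients are comparable),
and the categorical age (reference: adult; age increments each January as a
difference of calendar years), land cover (reference: forest) and TPI
landform (reference: canyon). TRI is screened out upstream when it
correlates with slope beyond |r| > 0.55 (strict inequality, tiny float
guard), with slope preferred as the more interpretable variable.

Every model carries crossed random intercepts for bird and month, fitted by
Laplace-approximate maximum likelihood: penalized IRLS/Newton for the joint
(β, u) modes inside a Nelder-Mead search over the two log-SDs (floor 10⁻⁴,
so zero-variance data degrade gracefully to plain logistic regression; the
fit then matches `statsmodels` Logit to < 10⁻³). The Laplace log-likelihood
is ℓ(β̂, û) − ½û′Σ⁻¹û − ½log det(H_uu) − ½Σ_j q_j log σ_j². Fixed-effect
standard errors are Wald, conditional on the variance estimates, from the
full penalized Hessian. On simulated crossed-design data the fit agrees
with lme4's `glmer` to ~0.01 in coefficients and random-effect SDs and
~10⁻³ in log-likelihood (cross-checked in the test suite via Rscript).

All-subsets search fits every combination of the candidate terms
(categoricals as blocks; random effects always present; ≤ 8 terms = 256
subsets), ranks by AICc = −2 logL + 2k + 2k(k+1)/(n−k−1) with k = fixed
effects + 2 variance components and n = rows, and computes Akaike weights.
Subset fits warm-start from the full model's variance estimates. Models
with weight ≥ 0.01 are combined by full (zero-substitution) averaging: a
term absent from a model contributes 0 with zero conditional variance, and
the adjusted SE is √(Σᵢ wᵢ(SEᵢ² + (βᵢ − β̄)²)) over renormalized weights. No
multiple-testing adjustment is applied; p-values are reported raw.

## The synthetic-data generator

The generator defines the study conditions for every test. It emulates:

* **Terrain** — a band-passed spectral random field with characteristic
  ridge wavelength 8 km plus a 10% power-law texture floor, rescaled to
  900 m relief on a 1024 × 1024 grid of 240 m cells (~246 km extent).
  This "basin-and-range" construction matters: it gives hillsides whose
  aspect is spatially coherent over ~1 km, realistic slope distributions
  (median ≈ 6°, max ≈ 25° at the 240 m cell scale) and all four TPI
  landform classes. A pure power-law field concentrates gradients at the
  finest scale, so aspect decorrelates within a single 15-min step and
  aspect selection becomes statistically invisible. Land cover is a
  smoother field thresholded at the quantiles of the requested class
  fractions (semidesert/forest/rock vegetation/shrubland–grassland,
  default 55/10/15/20%).
* **Movement** — four states parameterized by median speed / median |turn| /
  median AGL of (5, 131°, 14 m), (9, 115°, 11 m), (45, 96°, 108 m),
  (90 km/h, 76°, 450 m): two slow, tortuous, low-AGL states (perching and
  low hunting read-outs) and two fast, direct, high-AGL transit states.
  Speeds and AGL are log-normal around those medians (log-sd 0.5–0.8);
  turning angles are a state-characteristic magnitude with symmetric random
  sign and tight wrapped-Cauchy noise (ρ = 0.85). The sign-symmetric form
  keeps the median turn pinned at the reported value without welding the
  dispersion to it — a median-pinned one-parameter wrapped Cauchy is so
  dispersed that per-segment median turns become pure noise and the states
  are unrecoverable even in principle.
* **State dynamics** — a Markov chain whose diagonal encodes mean dwells of
  (90, 70, 12, 8) fixes and whose stationary distribution approximates the
  58/39/2/1% point shares; the dwells reproduce the reported ratio of
  points to segments (~65). At every fix the transition row is tilted by
  exp(βⱼ′x) of the local Gelman-rescaled covariates, with the low states
  preferring high, steep, north- and west-facing ground (state 1:
  elevation 1.5, slope 1.2, northness 0.8, eastness −0.5; state 2 shares
  the elevation and eastness tilts with weaker slope 0.4 and northness
  0.4, so the within-band contrast has a generating truth: the
  perching-like state concentrates on steeper, more north-facing
  hillsides). These tilts are
  deliberately stronger than the fix-level marginal effects a fitted model
  reports: bouts persist for hours, so on the order of only hundreds of
  independent bout choices carry habitat signal per simulated dataset, and
  weak tilts would be statistically invisible at that effective sample
  size. The mixed-logistic machinery itself is validated separately on
  directly simulated logistic data with the reported effect sizes
  (elevation 0.40, northness 0.14, eastness −0.12, slope 0.19; random-
  intercept SDs 0.5) as the generating truth.
* **Sampling and contamination** — 15-min daytime fixes (40/day starting
  15:00 UTC ≈ 07:20 local solar), Gaussian position noise (10 m), and an
  optional contamination pass injecting exact counts of 2D fixes, high-DOP
  fixes (HDOP or VDOP uniform on [10, 25]), and night fixes (drawn from the
  first two tracking hours and shifted 8 h earlier, keeping timestamps
  unique and on the 15-min comb so the subsampler is unaffected). The three
  flag sets are disjoint and returned as a per-fix ledger, making filter
  tests exact.

What the generator does **not** emulate: updraft or soaring energetics,
altitude-dependent GPS error, 30-s burst sampling, inter-bird behavioral
heterogeneity beyond the shared state model, temporally varying habitat
preference, and real landform geometry beyond second-order spectral
structure. Passing tests therefore demonstrate that the pipeline recovers
the structure this model family can express — not that real eagle data
contain exactly four states, nor that real habitat effects match any
particular magnitude.

Tracks that would leave the raster reflect at the boundary (billiard-style,
documented behavior, never an exception); the default domain is large
enough that reflections are rare even for the 20-km steps of the fastest
state.

## Problem sizes and determinism

The validation experiments run at deliberately chosen scales: 8 birds ×
9 000 fixes (~2 600 segments) for the end-to-end recovery runs; 100 seeded
series (n = 200) for changepoint recovery and the matched stationary nulls;
100 feature sets of 2 000 segments for elbow selection; 10 replicates of
n = 20 000, 40 birds for mixed-logistic recovery. Every random quantity
derives from an explicit seed; identical seeds give byte-identical rasters,
tracks, and fits.

## Known limitations

* The windowed BIC table uses a ρ grid rather than continuous optimization;
  break/model selection is insensitive to this, but per-window parameter
  estimates can be off by up to the grid spacing in ρ.
* The Laplace approximation biases variance components slightly downward in
  heavily unbalanced binary data, as with any Laplace-ML GLMM.
* The elbow criterion assumes nested cluster structure (multiplicative WSS
  decay); for overlapping elongated clusters no automated elbow is
  reliable, and the strength flag should be heeded.
* Per-fix habitat models inherit serial dependence within segments; SEs are
  conditional on the random-effect structure absorbing it, which is the
  standard but imperfect practice.
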