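# eaglestates

Behavioral-state inference for raptor GPS telemetry, and behavior-specific
habitat association. The package implements a complete, tested pipeline of
the kind used to study how golden eagles (*Aquila chrysaetos*) use desert
landscapes:

1. **Filtering** — remove 2D fixes and fixes with HDOP or VDOP ≥ 10,
   subsample to a 15-min interval, keep only fixes between civil dawn and
   civil dusk (solar elevation ≥ −6°, NOAA ephemeris), drop hatch-year
   fixes before first independence (> 10 km from the natal nest), and keep
   altitudes above ground level (AGL = GPS altitude − DEM elevation) in
   [−50 m, 4 000 m].
2. **Behavioral change point analysis (BCPA)** — persistence velocity
   *V*·cos θ is modeled within a sliding 30-point window as a Gaussian
   series with mean μ, standard deviation σ, and autocorrelation ρ (gaps
   enter as real exponents, X_i | X_{i−1} ~ N(μ + ρ^{Δt}(X_{i−1}−μ),
   σ²(1−ρ^{2Δt}))). Eight models — every subset of {μ, σ, ρ} changing at a
   candidate break — are compared by BIC; windows vote for break positions
   and votes are consolidated into changepoints.
3. **State clustering** — each segment is summarized by its median speed,
   turning angle, and AGL; the number of states is chosen by the elbow of
   the WSS curve; segments are clustered by k-means and renumbered
   deterministically (low/high AGL bands, more tortuous low cluster first).
   State differences are tested with tie-corrected Wilcoxon–Mann–Whitney z.
4. **Habitat models** — three paired mixed logistic regressions (low- vs
   high-altitude states; state 1 vs 2; state 3 vs 4) with crossed random
   intercepts for bird and month, Gelman-rescaled continuous predictors
   (x′ = (x−x̄)/2s), all-subsets AICc ranking, and full (zero-substitution)
   averaging of models with Akaike weight ≥ 0.01.

Because raw eagle telemetry is withheld for nest-site safety, the package
ships a first-class synthetic-data generator: spectrally synthesized
basin-and-range terrain plus four-state correlated-random-walk tracks
(two slow/tortuous/low-AGL states, two fast/direct/high-AGL states) with
habitat-tilted switching and a per-fix contamination ledger, so every stage
has an exact recovery test.

## Worked example

```python
import eaglestates as es
from eaglestates.clustering import (kmeans_cluster, segment_features,
                                    select_k_elbow, standardize_features,
                                    wss_curve)

land = es.make_landscape(es.LandscapeConfig(seed=11))
sim = es.SimConfig(n_birds=8, fixes_per_bird=9000, seed=11)
fixes, truth = es.simulate_tracks(land, es.default_states(), sim)
fixes, ledger = es.corrupt_fixes(fixes, sim)

pre = es.run_preprocess(fixes, land.dem)
print(pre.ledger)
# {'input': 72000, 'removed_quality': 4320, 'removed_subsample': 0,
#  'removed_daylight': 2880, 'removed_independence': 0, 'removed_agl': 0,
#  'output': 64800}

seg = es.run_segmentation(pre.steps)
feats = segment_features(seg.segments, seg.steps)
X, _, _ = standardize_features(feats)
elbow = select_k_elbow(wss_curve(X, k_max=10, seed=0))
assign = kmeans_cluster(feats, 4, seed=0)
print(len(seg.segments), round(assign.silhouette, 3))
# 2652 0.521
print(assign.centers.round(1))
#    state  med_speed  med_turn  med_agl
# 0      1        5.1     129.0     14.1
# 1      2        8.5     114.8     11.9
# 2      3       28.6     101.5     62.4
# 3      4       58.9      84.8    251.2
```

The filter ledger accounts for every removed fix (4 320 failed the
quality filter — exactly the injected 2D and high-DOP fixes — and 2 880
fell outside civil daylight). The four cluster centers reproduce the
generating state structure: two low-altitude states separated by speed and
turning angle (the slower, more tortuous one is state 1) and two
high-altitude, fast, directional states. Attaching terrain covariates and
fitting the low-vs-high mixed logistic model recovers the generating
habitat preference (positive elevation and slope coefficients: the
low-altitude behaviors concentrate on high, steep ground).

A thin CLI mirrors the stages: `eaglestates simulate|preprocess|terrain|
segment|cluster|model --help`.

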