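# Methods

This note documents the models, defaults and design decisions of
`firehist`. It states no numbers that the test suite or
`scripts/acceptance.py` do not themselves compute.

## Scene model (synthetic generator)

The generator emulates the statistical structure the analysis assumes,
not radiative physics.

**Landscape.** Land cover is a thresholded, Gaussian-smoothed random
field (correlation length `patch_scale_px`, default 8 px), giving
contiguous forest patches whose areal share equals `forest_fraction`
(default 0.7) up to ties. The management-zone map is an outer
*peripheral* ring (10% of the short grid side) with the interior split
into *service / buffer / community / core* strips; all five zones are
present on any grid large enough to hold the ring.

**Reflectance.** Per cover class, NDVI and NBR follow an annual harmonic
(mean, amplitude, peak month; forest 0.70/0.06, savanna 0.35/0.22 for
NDVI — evergreen-leaning dry forest is weakly seasonal while savanna is
strongly seasonal; both peak in the wet season). No field-measured
pre-fire index levels are assumed; the baselines are configurable
defaults. Red reflectance is held at
0.08 and NIR/SWIR2 are back-solved from the target NDVI/NBR, so indices
recomputed downstream equal the simulated series exactly. Reflectance is
simulated directly at surface-reflectance scale (the analysis consumes
ratio indices only). Observation noise (sd 0.05, index scale) and
missing-at-random cloud gaps (10% per pixel-month, shared across bands)
are applied last; clouds are not spatially correlated, which suffices to
exercise gap handling but understates real cloud structure.

**Fires.** The default schedule mimics an escalating fire regime: two
small events in September/October 2014 (8 and 10 ha), then 50 ha (2017),
25 ha (2018), 120 ha (2019) and 250 ha (2021), the later events seeded
and grown preferentially inside earlier scars (`overlap` 0.2–0.6) so the
landscape accumulates one-, two- and three-burn classes. Scars are grown
by randomized Prim expansion over forest pixels, so they are connected
and organic. Scheduling is restricted to the May–October dry season.
At a fire, NDVI steps down by 0.35 (first burn) or 0.15 (repeat burns —
less live canopy remains to lose) and, by default, never recovers
(`recovery_rate = 0`). NBR drops at the fire month by exactly
`dnbr_first + dnbr_increment × (prior burns)` (0.45 + 0.10 per prior
burn; severity grows with burn number) relative to the previous month,
then the char signal fades at 15%/month toward a permanently lowered
level (0.05 per burn). Seasonal amplitude is left unchanged after fire,
consistent with the additive season-plus-trend model the detector fits.

**Footprints.** `n_footprints` (default 1500) samples at forest pixels,
acquisition months uniform over 2019–2022, eight orbits, dry/wet season
label from the calendar month. Metrics are
`class baseline + β_fires·n_fires + β_months·months_since + zone offset +
season offset + noise`, clipped to their physical ranges. The fixed-effect
defaults are effect sizes typical of fire-degraded dry-forest structure
(PAI −0.2, CC −0.071, CH −0.114 per fire; months-since-fire 0 for
PAI/CC and −0.041 m for CH — standing dead trees fall over time). Noise sds (PAI 0.5, CC
0.07, CH 0.45) are set so the default scenario has the intended power
structure: strong significance for the PAI/CC fire effects, moderate for
CH. Zone/season random sds default small (these grouping factors are
expected to explain little variance relative to burn history). Quality flags fail at 5%.

Everything is driven by one seed through independent per-stage
`SeedSequence` streams; runs are bitwise reproducible.

## Index layer

NDVI = (NIR−Red)/(NIR+Red), NBR = (NIR−SWIR2)/(NIR+SWIR2). dNBR is
**pre minus post**, so fire-driven vegetation loss is positive — the
direction the 0.2 burn threshold requires. Division-by-zero pixels are
masked, never clamped. Monthly median composites take the per-pixel
median of unmasked observations and stay masked where nothing was
observed. The monthly dNBR series differences each month's NBR against
the most recent unmasked prior month within 3 months, recording that
bridge month, so a cloud-hidden pre-fire month does not erase the
fire-month spike; a spike first observed after a gap is dated to the
earliest gap month consistent with the break's confidence interval.
Event severity is the per-pixel maximum dNBR over the fire month's
observations (reported as max dNBR; burn-ratio peak during the fire
month).

## Break detection

Per pixel, observed months only (gaps are absent, never interpolated, so
clouds cannot fabricate breaks):

```
y(t) = trend_j(t) + Σ_{k≤K} [a_k sin(2πkt/12) + b_k cos(2πkt/12)] + ε
```

* Harmonic order K = 2 (captures the single wet/dry cycle plus
  asymmetry).
* Trend breakpoints by exact dynamic programming over per-segment
  linear-fit costs (prefix sums, O(n²), numba-compiled); on small series
  the DP provably matches exhaustive search, which the tests verify.
* Season and trend are estimated by alternating the harmonic fit and the
  segmentation (2 iterations; the zero-break case is a fixed point of the
  first iteration).
* Number of breaks (≤ 4) chosen by BIC on the deseasonalised RSS. BIC
  was selected over stricter penalties after measuring operating
  characteristics on study-like series (456 monthly observations, noise
  sd 0.05, 10% missing): it recovers small repeat-burn steps far more
  often while keeping the per-pixel null false-positive rate at ~1%,
  which is far too dilute spatially to survive the 5-ha minimum mapping
  unit. The LWZ criterion remains selectable.
* **Minimum segment length: 8 observations** (absolute, not the common
  h = 0.15 fraction). With a 456-month archive a 0.15 fraction would
  forbid any break in the last ~68 months — exactly where an escalating
  fire regime puts its events, including a final fire 15 months before
  the series end. Fractional values < 1 are still accepted.
* Confidence interval for a break date by RSS inversion: the chosen break
  is repositioned over admissible locations (others fixed) and the CI is
  the contiguous run whose RSS stays within an F-quantile bound of the
  minimum; for a noiseless step it collapses to the true month. The
  interval's lower edge is the first calendar month after the last
  pre-break observation, so unobserved gap months are covered. This is a
  simpler, testable substitute for asymptotic breakpoint theory and tends
  to be conservative.
* "Negative break" = step of the fitted trend level at the break < 0.

## Fire rule and spatial post-processing

A pixel is a fire candidate iff a negative NDVI break has max dNBR ≥ 0.2
within its 95% CI; the fire month is the argmax month (earliest on
ties). Candidates are binned by fire month and grouped into connected
components (4-neighbour rook connectivity by default; the pipeline
additionally bridges one-pixel cloud holes when forming events — the
grouping primitive itself defaults to pure connectivity). Events under
5 ha (56 px at 30 m are kept, 55 px removed) are eliminated before
refinement, and the filter is not re-applied afterwards.

**Perimeter refinement** is the automated stand-in for manual confirmation
against high-resolution imagery: the mean-composite NDVI difference across the fire month
(up to 3 months each side — fire signals persist, the pre-fire surface is
stable, and averaging suppresses single-composite noise) is segmented
with SLIC; segments dominated by the candidate set and segments clearly
outside train a classifier (logistic by default here; the forest base map
uses the small feed-forward network); the burn threshold on differenced
NDVI is authoritative over the classifier, and sits asymmetrically near
the unburned level (`background + max(0.05, 0.25·contrast)`, with the
background taken as the surround's upper quartile) because re-burned
ground steps less than first-burned ground and strongly seasonal savanna
would otherwise drag the background down. Pixels of boundary-straddling
segments are re-decided individually and no observed pixel below the
threshold is ever kept. An event whose burn/surround contrast is under
0.1 is judged a non-fire artefact and dropped. Refined fragments of one
scar that regrow into overlapping perimeters are merged per month.
Provenance (rule vs refinement) is kept per pixel.

## History and summaries

Events accumulate chronologically into per-pixel burn dates (strictly
increasing), counts and per-burn severity; pixels outside the forest base
map carry no history. Months-since-fire uses the sentinel −1 for
never-burned (distinct from 0 = burned in the reference month).
Landscape areas per burn-count class (class 0 included) sum exactly to
the forest-mask area. Per-event summaries report the previously-burned
fraction and its recency breakdown over a configurable (min, max) month
window (default 1–60 months, the "one-to-five years prior" style
statistic). Severity-by-burn-count attributes each pixel's k-th-burn
dNBR to class k, not the lifetime maximum.

## Structure statistics

Kruskal–Wallis (ties-corrected H, χ² p) and Dunn's test (pooled-rank z,
Bonferroni multiplied p capped at 1) are implemented from the rank
formulas so that brute-force oracle tests are meaningful; scipy serves
only as an independent cross-check in the tests. The linear mixed models
delegate to statsmodels `MixedLM` with crossed random intercepts for
season and zone expressed as variance components; fitting is REML, and a
singular fit (variance component at the boundary, or non-convergence) is
reported in the result rather than hidden. `n_fires` enters the model as
a numeric covariate (matching single-coefficient reporting) while the
group tests treat burn counts as ordinal categories. By default the
models are fitted on burned footprints only, where months-since-fire is
well-defined; `include_unburned=True` codes never-burned rows as
`n_months = 0` instead. The peripheral zone is excluded from all
statistics. The recovery assessment labels each fixed effect
declining/flat/recovering at α = 0.05.

## Problem sizes and numerical choices

The benchmark scene is 100×100 px (30 m, 900 ha) over 456 monthly
composites; break detection over ~7000 forest pixels takes seconds per
archive thanks to the numba DP. Acceptance-style simulations use 20
no-fire replicates for false positives, 100-replicate series simulations
for break power, 1000 null replicates for rank-test calibration and 200
footprint redraws for mixed-model coverage. Ties in the dNBR argmax take
the earliest month; degenerate inputs (all-masked pixels, series under
24 observations, single-class training labels, empty event lists) are
either rejected with a clear error or handled by documented conventions
(vacuous precision/recall = 1.0 with a note).

## What passing tests do and do not show

The generator's fires are step changes with no recovery and its clouds
are independent per pixel-month; real archives add sensor
harmonization artifacts, spatially correlated clouds, phenological
anomalies (droughts) and gradual degradation, any of which can produce
breaks the synthetic tests never see. Likewise the footprint model is
linear with Gaussian noise; real GEDI metrics have geolocation error and
waveform-dependent biases. Passing the suite therefore demonstrates the
pipeline's correctness and calibration under its stated model, not field
accuracy on real imagery.

## Known limitations

No atmospheric/topographic correction or cross-sensor harmonization; no
sub-monthly fire dating; no seasonal-component break detection; no
spatial autocorrelation between footprints; multi-month "probable fire
periods" are split at calendar-month boundaries (adjacent-month dating
ambiguity is tolerated to ±1 month at evaluation).
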