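# firehist

Fire-history reconstruction from multidecadal optical satellite time
series, and assessment of fire effects on forest structure from
spaceborne-lidar footprints.

`firehist` targets the situation of a protected tropical dry forest (a
forest/savanna mosaic of a few thousand hectares observed at 30 m
resolution for ~37 years) where fires are recent, escalating, and
confined to the late dry season. It answers two questions:

1. **When and where did it burn?** Per pixel, the monthly NDVI series is
   decomposed BFAST-style into harmonic seasonality and a piecewise-linear
   trend; dated negative trend breaks are matched with spikes in the
   differenced Normalized Burn Ratio (dNBR). A pixel is classified as
   burned when a negative NDVI break is accompanied by dNBR ≥ 0.2 within
   the 95% confidence interval of the break. Candidate pixels are grouped
   into per-month connected components, filtered at a 5-ha minimum mapping
   unit, and refined by supervised object-based classification (SLIC
   segmentation + a small feed-forward classifier) of the differenced NDVI
   image bracketing each fire. The result is a dated fire-event catalog
   and per-pixel burn-history layers (burn count, burn dates, months since
   fire, maximum dNBR severity).
2. **What did fire do to the forest?** GEDI-like footprints carrying
   plant area index (PAI), canopy cover (CC) and canopy height (CH) are
   filtered (quality flag, forest base map, exclusion of the peripheral
   management zone), joined to the burn history at their acquisition
   dates, and analysed with Kruskal–Wallis tests, Dunn's post-hoc test
   with Bonferroni correction, and linear mixed models
   `metric ~ n_fires + n_months + (1|season) + (1|zone)` fitted by REML.

The core model per pixel is

```
y(t) = trend_j(t) + Σ_{k≤K} [ a_k sin(2πkt/12) + b_k cos(2πkt/12) ] + ε(t)
```

with `trend_j` linear within segments separated by breakpoints chosen by
exact dynamic programming over the residual sum of squares and an
information criterion (BIC by default), and break-date confidence
intervals by RSS inversion.

Because the archives such a study uses (Landsat, Planet, GEDI) cannot be
bundled, the package ships a first-class **synthetic scene generator**
with known ground truth: seasonal Red/NIR/SWIR2 reflectance over a patchy
forest/savanna landscape with a five-zone management map, a schedule of
escalating, overlapping late-dry-season fires that step NDVI down with
zero recovery and spike dNBR by a configured magnitude, cloud gaps, and
structure footprints whose metrics respond linearly to burn count and
time since fire. Every stage is tested against this oracle.

## Worked example

```python
from firehist import PipelineConfig, run, evaluate_against_truth

cfg = PipelineConfig(seed=1)
cfg.scene.seed = 1            # 100x100 px, 1985-2022 monthly, 6 fires
ctx = run(cfg)                # simulate -> indices -> basemap -> breaks
                              # -> detect -> history -> stats
ev = evaluate_against_truth(ctx)
print(ev["n_detected_events"], ev["precision"], ev["recall"])
print(ctx["summaries"]["landscape"])
print(ctx["recovery"][["response", "n_fires_effect", "n_months_effect"]])
```

prints (seed 1):

```
6 1.0 1.0
   burn_count  area_ha     share
0           0   373.50  0.596865
1           1    89.73  0.143391
2           2   124.56  0.199051
3           3    37.98  0.060693
  response n_fires_effect n_months_effect
0      pai      declining            flat
1       cc      declining            flat
2       ch      declining       declining
```

All six injected fires are recovered with their exact fire months; ~60%
of the forest base map is unburned while ~14/20/6% burned one/two/three
times (the escalating schedule re-burns earlier scars, so the two-burn
class outweighs the one-burn class); repeated fires significantly lower
all three structure metrics, while months-since-fire shows no recovery
signal for PAI and CC — the fire-vulnerability pattern of a
non-fire-adapted dry forest.

A CLI mirrors the stages (`firehist all --seed 1 --out run1`,
plus per-stage verbs `simulate composite basemap breaks detect history
stats evaluate` operating on a run directory).

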