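# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `dayspace`. Nothing here states an
empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## GPS processing

Streams are 10-s epochs of planar positions in metres on a local synthetic
CRS; one file is one person-day, so no midnight splitting exists. Geodesy is
deliberately absent: every operation downstream is metric (buffers,
bandwidths, grid cells), and lat/lon would add projection machinery without
adding anything testable.

**Gap imputation.** Proprietary study pipelines typically impute GPS gaps
with unpublished algorithms, so the package defines its own documented
stand-in with three config-exposed parameters:

| parameter | default | meaning |
|---|---|---|
| `stationary_radius` | 100 m | endpoints closer than this are "the same place" |
| `stationary_gap_max` | 240 min | longest gap filled as a dwell (earlier position) |
| `moving_gap_max` | 10 min | longest gap bridged by linear interpolation |

Dwell-type filling dominates by design because real missingness concentrates
in indoor dwell periods (building attenuation, phone charging). Leading and
trailing missingness is never filled — there is no bounding evidence.
Imputation is idempotent, never alters observed epochs, and only adds
epochs, so day coverage is monotone under it.

**Validity.** A day is valid with ≥ 6 h of post-imputation coverage. The
rule is read strictly as "< 6 h is invalid": exactly 2,160 epochs (6.00 h)
passes.

## Activity-space surfaces

All surfaces live on a shared 50 m grid (`GridSpec`), origin snapped to a
multiple of the cell size so independently constructed grids align
cell-for-cell; cells are half-open squares and membership everywhere is by
cell-center test, which gives one consistent zero-area convention and no
double counting on boundaries. The environment grid pads the region by 300 m
so no kernel mass at the default 250 m bandwidth is ever clipped.

**KDE (primary).** Every epoch, observed or imputed, carries one unit of
time (all fixes equal; no dwell weighting). The kernel is the quartic
(biweight) `K(d) ∝ (1 − (d/h)²)²` for `d < h` — the kernel of the common
desktop GIS implementations — switchable to a Gaussian with σ = h/2
truncated at h. Two numerical choices matter:

- *Evaluation at cell centers*, not integrated over cells. At 50 m cells
  against a 250 m bandwidth the discretization error is small and uniform;
  the brute-force oracle tests pin the implementation to the same
  definition at 1e-9.
- *Per-epoch normalization before accumulation.* Without it, epochs near
  the grid edge (or with heavily clipped kernels) would contribute less
  than one time unit and distort relative time weights. After
  accumulation the surface is renormalized to sum to exactly 1; the
  `TimeWeightGrid` constructor asserts `Σw = 1` within 1e-9.

**Daily path area.** Successive epochs are connected in time order into a
polyline, buffered by 250 m (matching the KDE bandwidth), and cells whose
centers fall inside share weight uniformly — the conventional daily-path
exposure definition specifies geometry, not weights, and uniform weighting
is the standard reading. Observed gaps longer than 5 min split the route so
no corridor is fabricated across unobserved time. A single-epoch day
degenerates to a disc.

**Residential buffers.** A static comparator anchored at home: a euclidean
disc (800 or 1600 m) or a network service area — all points within the
radius of walking distance along the street lattice from the node nearest
home, found by Dijkstra with partial-edge reach, buffered by one block
width. Real pedestrian network data is out of scope; the lattice is the
generator's street model.

## Exposure metrics

Layers and surfaces must share a `GridSpec`; there is no silent resampling.
The weighted-sum overlay `Σ_c w_c v_c` is linear in the layer and bounded by
the layer's range over positive-weight cells (a convex combination).

- **Street greenspace (%)** is defined only within 25 m of a street
  segment; covered cells take the length-weighted mean green % of segments,
  weighted by segment length within 50 m of the cell center. Cells off the
  walkable network are nodata. When a surface overlaps nodata, weights are
  renormalized over defined cells by default — the variable only exists
  near walkable roads, so the metric is exposure *conditional on time spent
  where it is defined*; treating nodata as 0 is available in config and
  would instead shrink the metric with off-network time.
- **Park distance (m)** is the per-cell-center distance to the nearest park
  entrance, euclidean by default; network mode snaps centers and entrances
  to street nodes (multi-source Dijkstra) and adds the snap legs.
- **Parks (0/1)** marks cells whose center lies in any park polygon. The
  daily binary metric is *any* positive-weight overlap with a park cell —
  a strictly-positive-area reading, since any overlapping cell has
  positive area.
- **Walkability (1–20)** assigns each cell the score of the tract patch
  containing its center.

## Accelerometry

Counts arrive as non-negative integers per 10-s epoch. Non-wear is a
maximal run of zero counts strictly longer than 60 min (361+ epochs); a
single nonzero epoch restarts the run — no spike-tolerance window is
applied because the rule as stated has none. Exactly 60 min of zeros is
wear. Validity requires ≥ 10 h wear (exactly 10 h passes).

Epoch classification scales the 10-s count by 6 to counts·min⁻¹ and applies
`METs = 1.439008 + 0.000795 × cpm`; an epoch is MVPA at ≥ 4 METs. The
boundary is read inclusively; since `(4 − 1.439008)/0.000795 ≈ 3221.37` is
not attainable by an integer count rate, ≥ vs > cannot differ on integer
data and the choice is immaterial. Classification happens at the 10-s level
with no 60-s re-integration, matching the epoch-sum definition of the day
total (minutes = epochs/6); a per-minute re-integration variant would only
need the config constants.

## Mixed models

The outcome is `log(MVPA minutes + 1)`. Zero-MVPA days break a plain log;
the +1 offset is exact at zero, bounded below, and has the interpretable
back-transform `exp(x) − 1`. The offset is config-switchable; it slightly
attenuates multiplicative effects (by a factor ≈ y/(y+1) at outcome level
y), which at ~30 min/day baselines is ≈ 3% of the coefficient — visible in
the calibration experiments as a small, coverage-preserving bias.

Person-mean centering: BS = person mean, centered on the grand mean of
person means (so the intercept refers to an average person; the paper-style
alternative without grand-mean centering only shifts the intercept);
WS = daily deviation, summing to zero within person by construction. The
binary park exposure is not person-mean centered in its WS term (raw 0/1,
for interpretability); a centered variant is a sensitivity switch.

Models are Gaussian linear mixed models with a participant random intercept
(statsmodels `MixedLM`), ML by default (REML in config; the intercept-only
ICC model always uses REML). CIs are Wald z on the log scale, exponentiated
afterwards; Satterthwaite/Kenward–Roger refinements are out of scope. Rank
deficiency is detected before fitting and reported with the aliased column
names. Interaction models add exposure × modifier products (dummy-expanded
for categorical modifiers) screened at p < 0.05 with no multiplicity
correction; simple slopes use the delta method
(`var = v_ee + m²v_ii + 2m·v_ei`) at −1 SD/mean/+1 SD for continuous
modifiers, and predicted trajectories hold other fixed effects at their
sample means and back-transform via `exp(x) − 1`.

## Synthetic-data generator

The generator's defaults encode the emulated study design: 55
participants × 3 waves (first trimester, third trimester, 4–6 months
postpartum) × 4 days (2 weekday + 2 weekend), a 10 km square region, 50 m
cells, 200 m street blocks, 1 km walkability tracts, 1–4 rectangular parks
with boundary entrances, waking window 14 h, walking speed 1.2 m/s, GPS
jitter SD 10 m. Covariate marginals mirror the cohort's descriptives (age
truncated-Normal(29.0, 6.1) at 18; 35% some college; 29% first-born; BMI
27/35/38% normal/overweight/obese; 36% employed; deprivation 1–10; cohesion
1–5; daily temperature Normal(19.9, 4.4) °C).

Movement is a deliberately minimal two-anchor model: dwell at home, an
L-shaped lattice walk to one secondary anchor, an optional park visit
(probability 0.5), return. This produces exactly the variation the exposure
metrics need — home dwell, travel routes, park exposure on some days — and
nothing more. Missingness is block-structured (contiguous deletions);
20% of days are degraded below the 6-h GPS rule, 25% below 10 h wear, and
30% receive a > 60-min zero block, so the exclusion ledger in the pipeline
is exercised at roughly the attrition level longitudinal field studies see.

Daily MVPA minutes are generated multiplicatively:
`exp(μ + b_i + log(θ_park)·park_ij + log(θ_walk)·walkdev_ij + ε_ij)` with
μ = 3.4 (≈ 30 min/day), `b_i ~ N(0, 0.5²)`, `ε ~ N(0, 0.6²)` — a 0.41
between-person variance share — and default θ_park = 1.25. The park/
walkability truth of each day is computed *by the pipeline's own KDE
overlay* on the generated track, so parameter-recovery tests close the loop
through the actual exposure code. Counts realise the drawn minutes exactly:
a Poisson(30) baseline (~180 cpm, well below the cut point) with contiguous
blocks of 800+ count epochs (~4,800+ cpm), so on non-degraded days the
processing chain recovers the truth to within one epoch (1/6 min).

`simulate_panel` draws person-day panels directly from the same outcome
model, skipping the spatial stages; the Monte-Carlo calibration experiments
(100 CI-coverage replicates, 200 null replicates, ICC recovery) run at the
study's size — 55 participants × 8 valid days — which keeps the whole
battery around a minute while matching the inferential setting the
full pipeline produces.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real street topology and land cover, GPS error
correlated with the environment (urban canyons), behaviourally driven
(informative) missingness, activity-type structure within the day (the
count process is a placement of MVPA blocks, not a behaviour model),
attrition structure beyond i.i.d. degradation fractions, and
exposure–covariate confounding (covariates are drawn independently of the
exposure process, so covariate-adjustment code paths are exercised but not
stress-tested against confounding).

## Known limitations

- The KDE treats all fixes equally; dwell-state weighting is out of scope.
- Wald z inference is anti-conservative at small cluster counts; the null
  calibration shows rejection rates near but slightly above 0.05 for
  person-level (BS) terms at 55 clusters.
- The network service area approximates entrance/home access by node
  snapping plus euclidean legs.
- Exposure metrics from different activity-space methods are reported under
  method tags but are not commensurable (e.g., residential buffers ignore
  the day's mobility entirely); cross-method comparison is a sensitivity
  exercise, not a validity check.
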