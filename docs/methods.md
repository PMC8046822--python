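# Methods

This note documents the models and procedures implemented in `zonesdm`,
the parameter choices that matter, the design of the synthetic study
generator, and the package's known limitations.

## The modelling problem

The package implements a presence/background (presence-only) species
distribution workflow specialised to *zoned* crop production: a "combined"
model pooling all presences, plus one model per named production zone.
Suitability is a function of 26 environmental predictors — bioclimatic
variables Bio1–Bio19 (WorldClim naming: Bio1–Bio11 temperature-derived,
Bio12–Bio19 precipitation-derived), elevation, slope, aspect, and four
soil properties (pH, CEC, bulk density BD, organic carbon OC). All grids
in a run share one planar geometry with square cells of side `cell_km`.

## Occurrence preparation

Cleaning drops records that fail, in order: (1) missing/out-of-bounds
coordinates; (2) collection year missing or before 2000 — a missing year
cannot certify recency, so it fails the recency rule rather than being
given the benefit of the doubt; (3) *reported* positional uncertainty
above 50 km (a missing uncertainty is kept — only a reported excess
rejects). The rejection log counts the first rule each record fails, so
cleaning is order-independent at the set level.

Thinning is greedy in stable input order: keep a point iff it is at least
`radius_km` (default 5) from every already-kept point. Greedy order makes
the result deterministic; O(n²) distances are fine at occurrence-set
scale. Distances are haversine for lon/lat data and Euclidean for planar
synthetic data, selected by the occurrence set's `metric` flag.

Area-weighted balancing caps each zone's point density (points per km²)
at the **median** density across populated zones; denser zones are
randomly (seeded) subsampled down to `ceil(cap × zone_area)`. The median
cap is one concrete reading of "area-weighted elimination"; it leaves at
least half of the zones untouched and never removes a zone entirely.

Background sampling draws exactly `ratio × n_presences` distinct masked
cell centres (one per cell, so no two background points extract the same
pixel), uniformly at random outside a `buffer_km` (default 10) exclusion
zone around all presences. Ratio 10 keeps table prevalence at 1/11,
a deliberate guard against inflating test metrics with easy absences.

## Collinearity screening

`vif(table, focal)` is the textbook variance inflation factor: OLS of the
focal column on all the others with intercept, `VIF = 1/(1 − R²)`, with a
`+inf` sentinel at numerically perfect collinearity (R² within 1e−12 of
1). Elimination drops the max-VIF variable (ties broken by name, so
reports are deterministic) until all retained VIFs are below 10.
VIF is computed on the model-fitting table (values at presence +
background points) because that is the matrix the classifiers actually
see; a whole-raster variant is available via the CLI `select-vars` on any
CSV of cell samples.

## Classifier families and evaluation

All families obey one contract: fit on a labelled predictor table, emit
scores in [0, 1].

* **RF** — `RandomForestClassifier`, 500 trees, √p features per split.
* **BRT** — histogram gradient boosting, learning rate 0.01, depth 3,
  up to 5000 rounds with the number of rounds chosen by an internal 10%
  holdout (early stopping), minimum 10 samples per leaf.
* **SVM** — RBF kernel, standardized inputs, cross-validated sigmoid
  probability calibration so scores are comparable to the tree families.

These are community defaults for suitability modelling; every value is
overridable through `ModelSpec`/`RunConfig.hyperparameters`.

Evaluation runs `n_reps` (default 100) stratified 70/30 train/test
splits. AUC is the Mann–Whitney form (ties count ½) computed from ranks.
TSS is sensitivity + specificity − 1; per replicate it is evaluated at
the replicate's own max(sensitivity+specificity) threshold, consistent
with the ensemble binarization rule, because no fixed evaluation
threshold is assumed. Degenerate single-class splits are redrawn
(impossible under stratification, guarded anyway).

## Ensemble

Members are admitted when their mean test AUC over the replicates exceeds
0.75; the deployed scorer per family is a refit on the full table (the
replicates estimate skill; the refit uses all information). Weights are
AUC shares, so the ensemble is `E = Σ AUCᵢMᵢ / Σ AUCᵢ` and always lies
between the member extremes cellwise. Binarization maximizes
sensitivity + specificity over the *observed* score values at the
presence and background points (exact, no grid), breaking ties toward the
smaller threshold (favouring suitability). The threshold is selected on
the full point set and then **frozen**: every scenario projection reuses
the baseline `t*`, so area changes are attributable to climate, not to
threshold drift.

## Variable importance

Permutation importance per variable and family: `1 − Pearson r` between
predictions on the intact table and on a table with that column permuted,
averaged over `n_perm` seeded permutations and clamped to [0, 2]
(2 = perfectly anti-correlated predictions). Pearson correlation is the
conventional choice; predictions, not labels, are compared, so importance
measures what the *model* relies on. Importances are averaged across the
families' full-table refits (matching what the ensemble deploys) and
normalized to percent contributions; group shares aggregate percents to
climate vs topography vs soil, reported as the climate : soil+topography
split. A variable can score high importance without being a true driver
if it proxies one — see the collinearity note under Limitations.

## Scenario projection and impact accounting

Delta downscaling is additive for every climate layer —
`future = obs + (gcm_future − gcm_baseline)` — with precipitation-type
layers (Bio12–Bio19) floored at 0 and soil/topographic layers passed
through unchanged. A multiplicative variant for precipitation is a
recognized alternative but is not the default, matching the additive
change-factor definition. Per zone and scenario cell, percent change is
computed **per GCM and then averaged** (an average of relative changes,
not the change of an average), spread is reported min–max, and GCM
agreement is the size of the majority-direction camp (zeros side with
the majority; exact ties are flagged). Zone shares are reported at one
decimal with full precision retained internally.

## The synthetic study generator

The generator is first-class code, not a fixture: it produces the study
conditions every downstream stage assumes.

* **Fields.** Each layer is Gaussian-filtered white noise (σ = 2 cells,
  wrap-around), z-scored, then affinely mapped to plausible measurement
  scales (temperatures ~N(20, 5) °C, precipitation ~N(900, 250) mm
  floored at 0, pH ~N(6, 0.8), ...). The correlation length (~2 cells) is
  deliberately short relative to zone size so each zone samples the full
  environmental range; with much smoother fields, zone mean suitability
  diverges between zones and the per-zone presence quota distorts what a
  model can recover.
* **Collinearity.** A target layer is rebuilt as
  `r·z(source) + √(1−r²)·residual` with the residual orthogonalised
  against the source, so the empirical correlation equals `r` exactly.
  The default configuration places one twin on a true driver at r = 0.95
  (VIF ≈ 10.3, so the screen eliminates exactly one of the pair) and one
  on a nuisance pair at r = 0.9 (VIF ≈ 5.3, retained) — both branches of
  the screen are exercised, and no twin sits on the *strongest* driver,
  which would split its importance credit and make the top-driver ranking
  unidentifiable.
* **Truth and presences.** True suitability is
  `logistic(intercept + Σ βᵢ zᵢ)` on z-scored layers. The canonical
  strong-signal configuration (`strong_signal_config`) uses a 64×64 grid
  of 10 km cells, five zones tiling the domain (a 3×2 tile grid; the
  sixth tile is unassigned "other" territory), 100 presences per zone
  drawn without replacement with probability proportional to truth, and
  β = (−4, +5, +4) on Bio1, Bio12, pH with intercept −4. The intercept
  puts the truly-suitable fraction near 27% of the domain — the share a
  national crop-suitability analysis typically reports — and the
  coefficient scale makes the truth surface sharp enough that the
  presence/background task is in the high-skill regime (the suitability
  oracle itself scores AUC ≈ 0.86–0.90 on these tables); with weaker
  coefficients no model, however good, can reach that range, because
  presences drawn proportionally from a diffuse truth overlap the
  background in environment space.
* **Background ratio at fixture scale.** A 64×64 grid holds 4,096 cells;
  after 500 presences and their 10 km buffers, fewer than 5,000 distinct
  cells remain, so the 1:10 design is geometrically infeasible *at this
  grid size* and the strong-signal fixture uses 1:5. Pipeline-scale runs
  keep the 1:10 default.
* **Futures.** Synthetic GCMs get a fixed bias field and fixed per-layer
  trend directions (temperature layers trend warm, precipitation drifts
  with GCM-specific sign), scaled by scenario severity (SSP126 0.5 …
  SSP585 2.0) and period progress (2030s 0.25 … 2090s 1.0) in units of
  each layer's spatial SD.

What passing tests on this generator do **not** show: skill on real
occurrence data (spatial sampling bias, non-logistic truth), spherical
geometry effects (synthetic grids are planar; haversine distances are
used only for lon/lat occurrence data), spatial autocorrelation structure
beyond low-pass noise, and any interaction between predictors (the truth
surface is additive on the logit scale).

## Numerical choices and degenerate inputs

* AUC from ranks (scipy `rankdata`), exact under ties; both classes
  required, else an error.
* Threshold candidates are observed scores; an all-identical score vector
  yields that score as the threshold with a warning.
* Zero-variance predictions give importance 0 with a warning; all-zero
  importance tables normalize to uniform percents with a warning.
* Percent change at zero baseline area returns NaN with a warning rather
  than raising, so scenario tables stay rectangular.
* Empty cleaning survivors warn rather than raise (pipelines decide).
* A single global seed expands into per-stage seeds through a fixed-order
  generator; family-level fitting seeds are derived with SHA-256 of
  "scope|family", never Python's salted `hash`.

## Problem sizes used in the test suite

Unit tests run on 16–64 grids and tables of tens to thousands of rows.
The recovery checks fit 3 evaluation replicates per family before the
full-table refit, and estimate the top-driver identification rate over
50 importance runs with one permutation each on a 1,500/1,000-row
subsample — correlation-based importance stabilizes quickly in rows, and
the 50-seed rate, not the per-run value, is the statistic of interest.
The demo pipeline (`demo_config`) runs a 40×40 grid, 3 zones, 20
presences/zone, a 2×2×2 scenario matrix and 3 replicates per family.

## Known limitations

* The VIF tie-break (lexicographic) can eliminate a true driver and keep
  its collinear proxy; downstream importance then credits the proxy. This
  is inherent to collinearity screening, not an artifact of the
  implementation.
* Importance of correlated retained predictors is split between them;
  group shares are more stable than single-variable ranks.
* The BRT family uses histogram-based gradient boosting; at very small
  tables (< ~40 rows) its internal holdout is meaningless and should be
  disabled via hyperparameters.
* `area_weighted_balance` assumes planar polygon areas (km² coordinates);
  for lon/lat zone polygons, areas would need projection first.
* Scenario means weight all GCMs equally; no skill weighting.
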