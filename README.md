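# zonesdm

Ensemble species-distribution modelling for **zone-level crop suitability**
under current and future climate. The package targets "terroir"-style
questions — e.g. which parts of a country can sustain a premium,
single-origin crop, how the answer differs between named production zones,
and how much of each zone's suitable area survives under climate-change
scenarios. It is aimed at climate-impact and agro-ecology researchers who
want the full workflow (occurrence cleaning through per-zone impact tables)
as reusable, tested library code rather than a one-off script stack.

## The method

Presence records are cleaned (coordinate validity, recency, positional
uncertainty), thinned to a 5 km minimum spacing, balanced across zones by
capping per-zone point density at the median, and complemented with
pseudo-absence background points sampled at a 1:10 presence:background
ratio outside a 10 km buffer around the presences.

Predictors (19 bioclimatic + 3 topographic + 4 soil layers) are screened
for collinearity with the variance inflation factor,

    VIF_i = 1 / (1 − R²_i),

where `R²_i` comes from an OLS regression of predictor *i* on the others;
the worst offender is dropped iteratively until all VIF < 10.

Three classifier families — random forest (RF), boosted regression trees
(BRT) and a support vector machine (SVM) — are fitted on replicated
stratified 70/30 splits (100 replicates by default) and evaluated with AUC
and the true skill statistic (TSS = sensitivity + specificity − 1).
Families whose mean test AUC exceeds 0.75 enter an AUC-weighted ensemble

    E = Σᵢ (AUCᵢ · Mᵢ) / Σᵢ AUCᵢ ,

whose continuous suitability map is binarized at the threshold `t*` that
maximizes sensitivity + specificity at the presence/background points.
Variable importance is permutation-based: `1 − cor(pred, pred_permuted)`
per variable and family, averaged across families and normalized to
percent contributions (with climate vs soil+topography group shares).

Future climate surfaces come from delta (change-factor) downscaling —
`future = observed + (GCM_future − GCM_baseline)` per climate layer, with
precipitation floored at 0 and soil/topography held fixed — across a
GCM × SSP-RCP scenario × period matrix. Impacts are reported per zone as
suitable area (km²), percent change per GCM then averaged, min–max spread,
and the number of GCMs agreeing on the direction of change.

A synthetic-data module generates the whole study environment (smooth
correlated environmental fields, rectangular zone tiles, a known logistic
truth surface, presences oversampled where truth is high, additive GCM
deltas), so every stage runs and is testable without any downloads.

## Worked example

```bash
zonesdm run-all --seed 1 --out runs/demo
```

runs the full pipeline on the built-in desk-scale synthetic study (40×40
grid of 10 km cells, 3 zones, 20 presences per zone, 2 GCMs × 2 scenarios
× 2 periods). Outputs land in `runs/demo/`. From a real run at seed 1:

`ensemble_combined.json` — the combined-model ensemble admitted RF and BRT
(mean test AUC 0.803 and 0.850), while the SVM fell below the 0.75 cutoff
and was excluded; Eq. weights are AUC shares (0.486/0.514), and the
baseline binarization threshold was t\* = 0.350.

`importance_shares_combined.json` — grouped permutation importance split
64.3 : 35.7 between climate and soil+topography, with soil pH the top
single predictor (20.7%).

`impact_summary.csv` (first row) — under SSP126 in the 2030s the combined
suitable area fell from 8,700 km² to a 2-GCM mean of 7,250 km²
(−16.7% mean change, both GCMs agreeing on the direction):

```
scope,scenario,period,baseline_area_km2,mean_future_area_km2,mean_percent_change,...
combined,SSP126,2030s,8700.0,7250.0,-16.67,...
```

Re-running the same command reproduces every output byte for byte; the
`manifest.json` records the config hash and per-stage seeds.

The same stages are available individually (`zonesdm simulate`, `zonesdm
prep clean|thin|balance|background`, `select-vars`, `fit`, `ensemble`,
`importance`, `project`, `impact`) and as library functions
(`zonesdm.clean_occurrences`, `zonesdm.vif_eliminate`,
`zonesdm.build_ensemble`, `zonesdm.delta_downscale`, ...).

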