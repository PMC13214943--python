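# Methods

## Problem and model

The pipeline asks whether population-level environmental exposure —
annual-mean UV index and PM2.5 ground concentration, assigned to cancer
cell lines ecologically via their cancer type's geographic aetiology —
adds predictive signal to a pan-cancer drug-response model over and above
per-cell-line mutational-signature activities, drug chemistry, and
proteomic features. Drug response is LN_IC50, the natural log of the
half-maximal inhibitory concentration in µM; larger values mean
resistance.

The predictive model is a gradient-boosted tree ensemble (squared-error
loss) over a min–max-scaled feature matrix of interaction records
(cell line × drug). Two generalisation estimates are reported:

* a **row-level 20% holdout** (the headline figure; cell lines appear on
  both sides, so it benefits from within-line information), and
* **5-fold cell-line-grouped cross-validation**, in which every record of a
  cell line falls in exactly one test fold. The grouped estimate is the
  conservative one; the suite asserts the holdout ≥ grouped ordering.

## Spatial interpolation

Measurement networks are treated as planar point sets in (lon, lat)
degrees: Delaunay triangulation (delegated to `scipy.spatial.Delaunay`),
then piecewise-linear barycentric interpolation at each 1°-grid cell
center, implemented in-repo (point location scans triangles in ascending
index order; the first containing triangle wins, which only affects
bookkeeping for queries on shared edges). Cells outside a network's convex
hull receive the value of the nearest point (planar Euclidean distance,
ties to the lowest point index). There is no spherical correction, no
antimeridian wrap, and no land mask; these are fidelity choices to the
described methodology, and they matter most near the poles and the ±180°
meridian. Grid-cell centers sit at half-resolution offsets
(−89.5…89.5, −179.5…179.5 at 1°), avoiding pole and meridian
degeneracies; the convention is a package choice since none is standard.

Correctness is established by property tests: exactness at vertices and
for affine fields (linear interpolation reproduces planes to machine
precision), convex-combination bounds, and agreement with a brute-force
oracle (exhaustive point-in-triangle search + plane solve) to 1e−9 on 100
random instances.

## Aetiology zones

The default zone table holds the eleven published bounding boxes (SKCM,
LUAD, LUSC, ESCA, HNSC, STAD, LIHC, BRCA, COREAD, BLCA, UCEC), normalised
to signed degrees; users may override or extend it via config. Zone
exposures are unweighted arithmetic means over all raster cells whose
centers fall inside the box — ocean cells included, since the source
method describes no land mask (a documented deviation risk). Codes without
a box fall back to the global **median** over all cells, following how
unlisted types are described as handled; the fallback is configurable.
Antimeridian-crossing boxes are rejected rather than silently wrapped.

## Feature matrix

Assembly order: chemistry inner join on drug (rows lacking descriptors
are dropped and logged per drug key), then left joins of the signature,
proteomic, and zone blocks, then imputation, then scaling — fill-then-scale,
so imputed zeros pass through the scaler like data. Zero imputation is the
default; feature-mean imputation exists for the sensitivity comparison of
attribution rankings (`attribution.compare_rankings`). Min–max scaling maps
each column to [0, 1] with constant columns sent to 0; the fitted
per-column (min, max) is retained for inverse transforms (round-trip
asserted to 1e−12). The scaler is fitted on the full matrix before
splitting, mirroring the described pipeline order; fitting on train only
is the statistically cleaner alternative and is available by scaling the
train split and transforming the rest with its `ScalerState`.

The holdout split is by row with |test| = round(n·fraction), seed 42 by
default. Grouped folds shuffle the distinct cell lines (seeded) and deal
them round-robin into k folds, balancing folds by group count; sklearn's
`GroupKFold` (which balances sample counts instead) serves as the
independent leakage cross-check in tests.

## Booster configuration

Defaults follow the studied setting: 600 trees, depth 7, learning rate
0.025, 80% row and column subsampling, histogram tree method, fixed round
count (no early stopping), squared-error loss (the loss is not stated in
the source; squared error is the natural choice for an R²/RMSE evaluation).
Training is single-threaded CPU by default so results are bit-reproducible;
a `device` flag exists for GPU but nothing requires it. `BoosterConfig.fast()`
(300 trees, depth 5, lr 0.1) is the desk-scale profile used by tests and
the analysis drivers, where cohorts are ~50× smaller than the source data
and the full setting would be needlessly slow and over-regularised.

## Attribution

Attributions are exact path-dependent TreeSHAP (the TreeExplainer
algorithm class): conditional expectations off the decision path are
cover-weighted over the training hessian sums stored in the model. The
implementation (`geopharm._treeshap`) parses the booster's JSON dump and
runs the polynomial-time path algorithm in float64, recomputing predictions
and the base value from the same parsed trees, so the local-accuracy
identity `base + Σφ = prediction` holds to ~1e−12 (float32 mixed routes
leave ~1e−5 discrepancies at these prediction magnitudes). Split
comparisons are made in float32 to mirror xgboost's traversal exactly.
Two independent cross-checks guard the implementation: xgboost's native
`pred_contribs` (agreement to float32 tolerance) and brute-force Shapley
enumeration over per-subset conditional expectations on tiny ensembles
(agreement to 1e−10).

Global importance is the mean |φ| over a seeded holdout sample (default
6000 rows or all available), ranked descending with lexicographic
tie-break. Stability bootstraps the attribution **rows** (not re-training)
100 times; each resample's ranking is compared to the full-sample ranking
by Spearman ρ, and top-10 consistency is reported both as exact-order and
as set identity, since "identical top-10" is ambiguous between the two.
Dependence exports pair each feature with a conventional interaction
colour feature (Zone_PM25↔MolLogP, TPSA↔Zone_PM25, SBS4↔SBS5, SBS18↔SBS4).

## Interaction screen

Simple univariate OLS of LN_IC50 on signature activity per (signature,
drug) pair, pooled pan-cancer (the source describes the screen only as
linear-regression-based with Pearson r; pooling is the default, and a
per-tissue stratified mode exists). Pairs need ≥ 20 observations (min_n is
a package choice; none is stated) and non-zero variance on both sides.
p-values come from the exact t transform of r with n−2 degrees of freedom;
the headline filter is raw p < 0.01, with BH q-values always appended but
never changing the flag. Under a simulated global null of 2000 independent
pairs, the realised false-positive fraction is asserted within
0.01 ± 3·√(0.01·0.99/2000).

## Synthetic data

The generator emulates the five source tables with known ground truth:

* **Environmental fields** — UV: 8·cos³(lat) plus a small longitudinal
  harmonic, clipped at 0 (peak ≈ 8 UVI at the equator, < 1 at high
  latitude); PM2.5: baseline 4 µg/m³ plus four Gaussian industrial
  hotspots (East Asia, South Asia, North Africa, a milder North American
  plume). Measurement points (default 1872 UV points over −55°…70°
  latitude; 19,605 near-global PM2.5 points over −60°…80°) carry the field
  value *noiselessly*, so raster error is purely interpolation error.
* **Cell lines** — zero-inflated gamma SBS activities (NMF exposures are
  sparse and non-negative); config-driven (code, signature) enrichment
  multipliers raise activity and detection probability for aetiology pairs
  (SKCM/SBS7a-d, LUAD+LUSC/SBS4, upper-GI/SBS18, BRCA+BLCA/APOBEC);
  clock-like SBS1/SBS5 are present everywhere. Proteomic features are
  independent Gaussians with 30% missingness — the joint distribution of
  real proteomics is unknown, so independence is the documented default.
* **Drugs** — the eight tabulated descriptors from drug-like ranges;
  count descriptors are integers, FractionCSP3 ∈ [0, 1].
* **Responses** — LN_IC50 = intercept + Σ planted effects + N(0, σ²), one
  row per (line, drug). Effects are evaluated on cohort-min–max-normalised
  feature values with shapes linear / threshold / U; the default table
  plants the qualitative structure the downstream stages must recover:
  TPSA U-shape, positive Zone_PM25, Zone_UV, MolWt and SBS4 effects,
  negative SBS18, MolLogP and SBS1 effects, and an SBS7a resistance
  threshold. Under the calibrated default the contributions are rescaled
  to carry 70% of the target variance (residual SD ≈ 1.51 log-µM) and the
  intercept centres the marginal at mean 2.81, SD 2.76 — the documented
  GDSC2-like regime in which the boosted model attains holdout R² ≈ 0.7.
  Per-feature contributions and the noise draw are stored in the output,
  so `intercept + Σ GT_* + GT_NOISE == LN_IC50` holds *exactly* and tests
  can reconstruct full decompositions.

What the generator does **not** emulate: correlated proteomic blocks,
tissue-specific drug-response structure beyond the planted effects,
dose–response curves upstream of IC50, trinucleotide mutation catalogues
(activities are drawn directly, not decomposed), and real geography
(fields are smooth closed forms). Passing tests therefore demonstrate that
the pipeline recovers what was planted under a known additive model — not
that the scientific findings transfer to real cohorts.

## Problem sizes

Tests and the analysis drivers use the desk-scale profile (200 cell lines
× 36 drugs × 64 proteomic features; 400/900 measurement points), with the
cohort-scale profile (948 × 36 × 1215; 1872/19,605 points) available as a
preset. The acceptance script generates ~100,800 records for the marginal
calibration check and n = 800 for the screen-recovery check.

## Known limitations

* Planar-degree geometry distorts distances with latitude; nearest-
  neighbour polar fill is crude. Kriging/spherical methods are out of scope.
* Ecological zone assignment is vulnerable to the ecological fallacy and
  confounding with tissue lineage; zone values are type-level constants.
* Attribution quantifies predictive contribution within this model, not
  causation.
* The screen pools pan-cancer by default and does not adjust for tissue;
  with real data this confounds lineage and exposure.
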