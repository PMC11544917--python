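# Methods

This note records the modeling choices behind `glucluster`: what each stage
assumes, the parameters that matter, what the synthetic cohorts do and do not
emulate, and the numerical conventions that make runs reproducible.

## Nocturnal segments and preprocessing

A segment is one night's interstitial glucose sampled every 5 minutes from
00:00 to 05:59 — 72 readings, attributed to the calendar date of the 00:00
start. Slot index = minutes-since-midnight / 5; slots without a sample are
missing. All glucose is in mmol/L and clipped to the common CGM detectable
range [2.2, 22.2] (40–400 mg/dL).

Quality rules, applied before imputation:

* **LONG_GAP** — any run of ≥ 3 consecutive missing readings rejects the
  night. Linear-neighbor imputation over ≥ 15 min of missing data would
  fabricate dynamics precisely where hypoglycemia detection needs them.
* **TOO_SPARSE** — strictly more than 10 % missing (≥ 8 of 72) rejects the
  night, however the gaps are scattered.
* **BOUNDARY_GAP** — a 1–2-point gap touching index 0 or 71 rejects the
  night: the imputation rule is defined only with a neighbor on each side,
  and we do not extrapolate.

Surviving 1–2-point gaps are filled with the arithmetic mean of the nearest
non-missing values to the left and right; both entries of a double gap take
the same mean. The operation is idempotent and never alters observed values.

**Nocturnal hypoglycemia (NH)** is glucose strictly below 3.9 mmol/L
sustained for at least 15 minutes. Three consecutive 5-min readings (indices
t, t+1, t+2) cover the interval [t, t+15) and are the default persistence
requirement (`min_run=3`); the stricter four-reading convention is available
via the same parameter. Labeling requires a fully imputed segment.

The panel splits 0.7/0.1/0.2 into train/validation/test by seeded shuffle
with largest-remainder rounding, independently within the NH-positive and
NH-negative pools, because all downstream modeling treats the two groups as
separate populations. Role sizes depend only on pool sizes, not the seed.

## Clustering

Training nights are vectors in ℝ⁷². The distance is plain Euclidean on raw
values: all series share units and a fixed time grid, and level differences
are clinically meaningful, so no normalization or warping is applied.

Ward's criterion merges, at each step, the pair of clusters whose union
minimally increases the total within-cluster sum of squared deviations from
cluster means. The implementation delegates to `scipy.cluster.hierarchy`
(Lance–Williams recurrence); stored merge costs are converted to the
variance increase ΔESS = d²/2, which is nondecreasing along the sequence.
The test suite verifies the merge sequence against a brute-force oracle that
evaluates every candidate pair's variance increase at every step. Merge
tie-breaking among exactly equal costs follows the library's ordering; such
ties have probability zero for continuous data. All other ties — medoid
selection, nearest-medoid assignment, k selection — break deterministically
to the lowest index / smallest value.

The number of clusters is the silhouette-score argmax over a configurable
range (default 2–10; ties to the smallest k), with the full per-k table
returned for expert inspection, and a fixed k available as an override.
Singleton clusters score 0 by convention; the all-singleton partition scores
exactly 0. Each cluster is summarized by its **medoid** — an actually
observed night, unlike a centroid — so "copied" forecasts are always
physiologically plausible traces.

Partition robustness is quantified by a noise-perturbation procedure: add
independent N(0, sd) noise (default sd = 0.3 mmol/L, 100 repetitions) to
every value, recluster, cut to the same k, and average the adjusted Rand
index against the unperturbed partition. The score is advisory; it gates
nothing downstream.

## Forecasters

All forecasters see only a night's first 72−h readings when predicting its
last h (direct multi-output strategy; h = 3 or 6 for the 15/30-min
horizons). Cluster assignment at prediction time likewise uses only the
first 72−h components of each medoid, so no future information leaks.

* **MTSC** copies the next h components of the nearest medoid.
* **WMTSC** weights every medoid's continuation by ω = softmax(1/d′). An
  exact match (d′ ≤ 10⁻¹²) takes weight 1 (shared uniformly among exact
  ties); the softmax is computed with the usual max-subtraction for
  stability, so a near-zero distance (e.g. 10⁻⁸) smoothly recovers the MTSC
  forecast. Note the inverse distances of typical prefixes are all ≪ 1, so
  the softmax is close to uniform and WMTSC behaves like an unweighted
  medoid average — visibly poor when clusters are far apart. This is a
  property of the weighting formula itself, reproduced faithfully.
* **Cluster-routed ensembles** fit one multi-output regressor per cluster on
  that cluster's members only. Random forests (300 trees, unlimited depth)
  are natively multi-output; gradient boosting (300 trees, depth 3, learning
  rate 0.1, squared-error loss) is inherently single-output, so one boosted
  model is fit per forecast step with shared hyperparameters. Clusters with
  fewer than 10 members fall back to a global model of the same kind. All
  hyperparameters are config-tunable (the validation split exists for that
  purpose); the defaults above are used throughout the shipped experiments.
* **Global ensembles** use identical feature/target construction on the
  whole training panel.
* **Holt** double exponential smoothing uses the classical initialization
  ℓ₁ = y₁, b₁ = y₂ − y₁ and no seasonal term (a 6-h nocturnal window has no
  seasonal cycle). (α, β) are grid-searched per night over
  {0.1, …, 1.0}² minimizing in-sample one-step-ahead squared error; SSE
  values within 10⁻¹² of the minimum count as tied and resolve to the
  smallest α, then β, so a constant night returns the smallest grid values.

## Metrics and benchmark

RMSE, MAE (mmol/L) and MAPE (fraction, with the 1/N mean normalizer) are
pooled over every forecast point of every evaluated night — one number per
(NH group, horizon, algorithm) — with per-series averaging available behind
a flag. Per-step MAE curves keep the step-wise resolution, indexed by
forecast step within the horizon; an alternative rolling-origin view
(forecast the last L points for varying L) is provided for the ambiguous
"error vs predicted length" reading. Each NH group is clustered and
evaluated independently. The default benchmark rows are MTSC, WMTSC, Holt,
global GBT, cluster-routed RF and cluster-routed GBT; a global RF is
available but off by default.

## Synthetic cohorts

The generator emulates the nocturnal pattern taxonomy with six archetype
mean curves: stable in-target (6.5), stable elevated (10.5), downward trend
(10.0 → 5.5), upward trend (6.0 → 11.0), a smooth cosine dip to 3.2 mmol/L
at index 36 with partial recovery, and a low drifting night (4.4 → 3.3).
Hypo archetypes sustain < 3.9 mmol/L for ≥ 3 consecutive noiseless points;
non-hypo archetypes never go below 4.4 noiseless, so ground-truth NH status
is unambiguous. Each simulated night adds

* a per-night level offset ~ N(0, 0.5 mmol/L) — between-night/between-patient
  level variability;
* stationary AR(1) noise with coefficient φ = 0.8 and innovation sd
  σ = 0.3 mmol/L — smooth, autocorrelated sensor-like error (stationary sd
  0.5 mmol/L);
* missingness: isolated points at rate 0.01 per index plus one 3–6-point
  outage in 5 % of nights, to exercise the exclusion filters.

These defaults were fixed once as plausible for real-time CGM error and are
not calibrated against any clinical dataset. The generator deliberately
omits meal/insulin physiology, circadian structure beyond the archetype
shapes, sensor drift and calibration artifacts, and realistic error-model
magnitudes (MARD). Consequently, passing tests demonstrate the correctness
and internal consistency of the pipeline and the qualitative behavior of the
algorithms under known heterogeneity — not clinical forecasting accuracy.

A caveat the benchmark itself exposes: with these conditions the AR(1) noise
floor (MAE ≈ 0.3 mmol/L at these horizons) dominates, and a night's pattern
is trivially identifiable from its 66–69-point prefix, so a global tree
ensemble recovers the routing internally and pre-clustering yields little or
no advantage over it for boosted trees — the cluster-routed RF, by contrast,
does lead several cells. Advantages of pre-clustering on real CGM panels
plausibly rest on pattern-conditional dynamics richer than this generator
emulates; demonstrating that gap is informative in itself and the relevant
comparison is left visible rather than smoothed over.

## Determinism and problem sizes

Every stochastic step takes an explicit integer seed: cohort generation,
splitting, stability perturbations, and tree ensembles. Identical
(config, seed) reproduces CSV artifacts byte for byte; the pipeline manifest
records the config hash and the seeds each stage consumed, and unchanged
stages are skipped on rerun. Shipped experiment sizes — 400-night recovery
cohorts, 600-night benchmark cohorts, a 240-night demo — were chosen so the
full study re-runs in minutes on a single CPU while keeping per-cluster
training sets comfortably above the fallback threshold.

## Known limitations

* Ward merge ties follow the linkage library's internal order (relevant only
  for exactly duplicated rows).
* The silhouette-selected k is a heuristic; the config override exists
  because visual/expert assessment may prefer a different granularity.
* Boundary-gap nights are dropped, not extrapolated; cohorts with systematic
  start-of-night dropout will lose those nights.
* MAPE is undefined at zero glucose; inputs are validated strictly positive
  (guaranteed here by the 2.2 mmol/L sensor floor).
* Tree ensembles cannot forecast outside the range spanned by their training
  targets, inheriting the detectable-range limits of the training data.
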