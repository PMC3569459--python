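# Methods

This note documents the models and procedures implemented in
`bioregionize`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic tests do and do not
demonstrate.

## Suitability models

Each species is modelled with a presence-only maximum-entropy model: a Gibbs
distribution `p(i) = exp(w·f_i)/Z` over the background (all grid pixels; at
a few hundred to ~1,200 pixels there is no reason to subsample background).
The fit maximizes the L1-penalized presence log-likelihood

    J(w) = (1/m) Σ_presences w·f_i − log Z − β Σ_j s_j |w_j|

* **Features.** Linear and quadratic terms of min-max-scaled predictors
  only. Full Maxent's "auto features" add hinge/threshold/product classes
  chosen by sample size; we deliberately restrict to linear + quadratic:
  the combination is deterministic, desk-scale, and sufficient to express
  the unimodal (Gaussian-like) climatic responses this pipeline assumes.
  This is a documented divergence from Maxent proper.
* **Penalty.** `s_j = sd_presences(f_j)/√m` (sample sd, floored at 1e-6)
  mirrors Maxent's default per-feature regularization scale, so a single
  multiplier β (default 2) is meaningful across features.
* **Optimizer.** Monotone proximal-gradient ascent with backtracking line
  search, started at `w = 0`; fully deterministic. Iteration stops when the
  objective improves by less than `tol` (default 1e-5) or after `max_iter`
  (default 500) steps. The recorded objective path is non-decreasing by
  construction, which the tests assert.
* **Output scale.** Projected maps are raw Gibbs probabilities rescaled by
  their maximum, giving values in (0, 1]. The downstream threshold rule
  depends only on ranks, and rank order is invariant to this rescaling;
  Maxent's logistic output is intentionally not reproduced.
* **Evaluation.** Ten seeded 70/30 splits of the presence pixels
  (train = ⌊0.7·m⌋); each replicate's AUC scores the held-out presences
  against *all* background pixels, matching the usual presence/background
  test-AUC construction. Because test presences are themselves background
  points, a perfect model scores slightly below 1.
* **Thresholding.** Maximum training sensitivity + specificity, with
  background pixels as pseudo-absences (presence-only data have no true
  absences); candidate thresholds are the observed suitability values and
  ties take the smallest threshold, so the rule is deterministic.
* **Filters.** Species enter modelling only with strictly more than
  `min_occ = 10` occupied pixels; fitted models are retained only with mean
  replicate AUC ≥ 0.70. Both boundaries are asserted by unit tests.

## Assemblages and clustering

Binary maps are stacked into a pixels × species matrix; pixels with
predicted richness below `min_richness` are discarded before clustering
because species-poor pixels produce a strong, misleading k-means signal.
The default threshold (25) is calibrated to a stacked flora of ~1,250
species; the scaled synthetic runs in this repository (~80 species) use
`min_richness = 5`, the proportionally equivalent choice.

Rows are Hellinger-transformed, `y = √(x/rowsum)`, so Euclidean k-means
operates on Hellinger distances and shared absences carry no weight.
Clustering is plain Lloyd k-means — initial centres drawn from distinct
data rows, no k-means++ — with the best squared error over `n_restarts =
100` seeded restarts. Two numerical details:

* When many transformed rows are exact duplicates, centres drawn from
  distinct row *values* (when enough exist) prevent coinciding initial
  centres; otherwise empty clusters churn without converging.
* An empty cluster is re-seeded from the farthest point of a donor cluster
  with more than one member, so the donor cannot become empty in turn.
* "Sum over the distances of data points from their cluster centre" is
  implemented as the sum of *squared* distances (the standard k-means
  objective); within-restart SSE is non-increasing and asserted as such.

**Choice of k.** The v-fold procedure of the statistical package originally
used for this analysis is not published in algorithmic detail; the
implementation here is a documented reconstruction. Rows are split into
v = 50 seeded folds; for each k, k-means (with a reduced restart budget,
default 10) is fitted on the training folds and the held-out rows are
charged the mean squared distance to their nearest trained centre;
`cv_error(k)` averages over folds. The chosen k is the smallest k whose
relative improvement `[cv(k) − cv(k+1)]/cv(k)` falls below the
error-disparity threshold (3% or 5%); if none qualifies, the largest k of
the grid is returned with a warning, and degenerate all-identical data
return the smallest k. Whether the original tool compared mean or total
cost, or compared to k+1 or to the best-so-far, is unknown; this
reconstruction is not asserted to be identical.

## Scoring

* **Moran's I for a categorical map** is not uniquely defined; the choice
  here is the size-weighted mean of per-region binary Moran's I values with
  classic (non-row-standardized) binary rook weights over the retained
  pixels. This matches the verbal definition — pixels of one region tending
  to be neighbours — and is flagged as a reconstruction. The permutation
  p-value is `(1 + #{I_perm ≥ I_obs})/(1 + n_perm)` with labels shuffled
  over pixels (default 999 permutations, seeded).
* **Agreement with a reference map** uses the confusion table on the union
  category set (zero-padded to square so marginals are well defined):
  per-category overlap = 100 × diagonal/row-total, Cohen's kappa globally,
  and one-vs-rest collapsed kappa per category. Verbal labels use the
  conventional bands (very poor < 0.2 ≤ poor < 0.4 ≤ fair < 0.55 ≤ good
  < 0.7 ≤ very good < 0.85 ≤ excellent), left-closed at the cut points —
  the prose convention is ambiguous exactly at the cuts.
* **Cross-scheme consistency** matches the cluster labels of two
  regionalizations one-to-one by maximum agreement (Hungarian assignment on
  the confusion table) and reports the matched percentage; it is symmetric
  and equals 100 exactly for identical partitions up to relabelling.
* **IndVal** follows the specificity × fidelity definition computed on the
  stacked *potential* matrix that was clustered (observed records are absent
  for many pixels; an observed-matrix mode is also supported). Values are
  reported on the 0–1 scale, with an optional ×100 output. No permutation
  significance test is attached.

## The synthetic world

The generator emulates the study conditions at desk scale: a 10×20 lattice
(200 pixels standing in for ~1,200), 80 virtual species (standing in for
~1,300), three true regions, and presence-only records thinned by a
sampling-effort field with optional intensively surveyed zones.

* **Climate.** Two predictors: a dominant north-south axis and a weak
  east-west axis (range 0.1 of the NS range), plus per-pixel Gaussian noise
  (sd = 0.04 of each range). The NS axis is a smooth sigmoidal staircase —
  climatic belts separated by narrow logistic ramps (width 0.02, snapped
  midway between lattice rows) with a small residual within-belt slope
  (0.05) — rather than a featureless linear gradient. This matters: with a
  purely linear gradient, species turnover is a continuum, the held-out
  clustering error keeps improving by more than 5% per added cluster, and
  *no* disparity threshold stops near the generating number of regions.
  Zonal belts are also the more faithful miniature of a continent whose
  regionalization is climate-driven.
* **Regions.** Each pixel joins the belt whose noise-free score level its
  noisy score is closest to. Noise can still disconnect a region, so the
  noise field is redrawn until a rook-adjacency flood fill certifies every
  region connected (at most 100 attempts, then an error). A noise sd of
  0.1 of the range makes this redraw fail for most seeds on the default
  lattice; 0.04 passes robustly, which is why it is the default.
* **Species.** Each species draws its niche optimum near the climate
  centroid of one region-affiliated pool (jitter sd 0.02 of each range) and
  occupies pixels with probability `exp(−d²/2σ²)`, where d is climate
  distance and σ = `niche_width` (default 0.1, in units of the NS range).
  Occupied pixels are recorded with probability
  `detectability × effort multiplier` (default 0.7, capped at 1). Each
  species consumes its own RNG stream, so species are decoupled and stages
  re-runnable.
* **What passing tests show.** Recovery runs demonstrate that the pipeline
  finds the generating number of regions and their extent when regional
  species pools are strong and climate is zonal — the analogue of the
  "strong signal" regime. Across seeds 1–10 the full pipeline at 5%
  disparity chooses k = 3 in seven cases and k = 4 (adjusted Rand ≥ 0.93)
  in three. They do not show how the pipeline behaves under continuous
  turnover with no regional pools (where a disparity rule on relative
  improvement has no elbow to find), under niche truncation, dispersal
  limitation, or record misidentification — none of which the generator
  emulates.

## Determinism and seeding

Every stochastic stage draws from a named RNG substream derived from a
single master seed (`(master, stage, unit)` → `SeedSequence`), so per
species evaluations, per-restart initializations, folds and permutations
are independently reproducible, and a full pipeline rerun with the same
seed is bit-identical apart from timing metadata.

## Known limitations

* The maxent variant is linear+quadratic only: no hinge features, no
  clamping, no extrapolation (MESS) analysis, no logistic output.
* The v-fold k-selection is a reconstruction (see above).
* Per-category kappa via one-vs-rest collapse need not match values
  produced by specialized map-comparison software on a different pixel
  universe.
* Subsampling retains a pooled fraction of in-zone records; per-species or
  per-pixel subsampling are plausible alternative readings and are not
  implemented.
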