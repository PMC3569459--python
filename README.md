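# bioregionize

Biogeographic regionalization from stacked presence-only species
distribution models.

## The problem

Delineating biogeographic regions — contiguous areas that share a
characteristic species assemblage — requires distribution data for a whole
flora or fauna on a common grid. For most taxa such data are spatially very
uneven: a few intensively surveyed countries and large gaps elsewhere.
`bioregionize` implements a pipeline that works around this: it models each
species' climatic suitability from the presence records that do exist,
projects the models over the full grid, stacks the thresholded predictions
into *potential* assemblages, and clusters the grid cells into regions from
those assemblages. It is aimed at macroecologists working with coarse
(~100 km) presence-only atlas and herbarium data.

## The method

Per species, a maximum-entropy (Gibbs) suitability model over the background
pixels,

    p(i) = exp(w · f_i) / Z,

is fitted by maximizing the L1-penalized presence log-likelihood

    J(w) = (1/m) Σ_presences w · f_i − log Z − β Σ_j s_j |w_j|,

with linear + quadratic features of min-max-scaled climate predictors
(collinear predictors pruned at Pearson |r| > 0.8), penalty scales
s_j = sd_presences(f_j)/√m and β = 2. Species with ≤ 10 occupied pixels are
excluded; model quality is the mean AUC over ten 70/30 presence splits
(test presences scored against all background pixels) and models with
AUC < 0.70 are dropped. Suitability maps are binarized at the threshold
maximizing training sensitivity + specificity and stacked into a pixels ×
species matrix; pixels with fewer than a minimum number of predicted
species are discarded.

Pixels are then clustered with k-means on Hellinger-transformed rows
(y = √(x/rowsum), so Euclidean distance equals the Hellinger distance and
shared absences carry no weight), taking the best of 100 seeded random
restarts per k. The number of regions is chosen by v-fold cross-validation
(v = 50): k stops growing at the first k whose relative held-out-error
improvement over k+1 falls below an error-disparity threshold (3% or 5%).
Results are scored with Moran's I spatial autocorrelation (size-weighted
mean of per-region binary Moran's I on rook adjacency, permutation p-value),
Cohen's kappa and per-region overlap percentages against a reference region
map, cross-scheme consistency under optimal label matching, and IndVal
indicator species (IndVal = specificity × fidelity).

A synthetic-world generator (`bioregionize.synthetic`) produces lattices
with zonal climate, known contiguous regions, region-affiliated virtual
species with Gaussian niches, and spatially biased sampling effort, so every
stage is testable offline against a known truth.

## Worked example

```python
from bioregionize.synthetic import WorldConfig, make_world
from bioregionize.pipeline import PipelineConfig, run_pipeline

world = make_world(WorldConfig(seed=1))          # 10x20 lattice, 3 regions, 80 species
config = PipelineConfig(
    occurrences=world.occurrences, climate=world.climate,
    schemes=(1.0,), disparities=(0.05,), min_richness=5, seed=1)
report = run_pipeline(config)
result = report["schemes"]["s100"]["disparities"]["disparity_0.05"]
print(result["chosen_k"], round(result["morans_i"], 2), result["morans_p"])
```

prints

```
3 0.84 0.001
```

The cross-validation selected k = 3 regions — the number the world was
generated with — and the recovered map is strongly spatially coherent
(Moran's I = 0.84; none of 999 label permutations reached the observed
value, p = 0.001). Comparing the recovered labels with the generating truth
gives an adjusted Rand index of 1.0 on this seed. The same pipeline run with
all four subsampling schemes of the intensively surveyed zone
(100/60/40/20%) assigns 84% of pixels to matching regions across schemes.

The same stages are exposed as a CLI:

```bash
bioregionize simulate --rows 10 --cols 20 --regions 3 --species 80 --seed 1 --out world/
bioregionize run --occurrences world/occurrences.csv --climate world/climate.csv \
    --grid world/grid.csv --min-richness 5 --seed 1 --out run/
```

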