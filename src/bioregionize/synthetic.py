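"""Synthetic worlds with known region structure.

Generates a small rectangular lattice with smooth climate gradients, a
contiguous "true" regionalization induced by the climate, virtual species
with unimodal (Gaussian) climatic niches, and occurrence records thinned by
a spatially biased sampling-effort field. Every downstream stage of the
pipeline can therefore be exercised against a known ground truth.

Design of the climate: a dominant north-south axis shaped as a smooth
sigmoidal staircase — distinct climatic belts separated by narrow logistic
ramps, with a small residual within-belt slope (think of zonal thermal belts
rather than a featureless gradient) — crossed with a weaker linear east-west
axis (continentality), plus seeded Gaussian noise. True regions are the
belts: each pixel joins the belt whose noise-free score level its (noisy)
score is closest to, which keeps regions spatially contiguous; because noise
can still break contiguity, the noise field is redrawn until a
rook-adjacency flood fill certifies every region connected (bounded number
of attempts). Species belong to region-affiliated pools: each draws its
niche optimum near the climate centroid of one belt, so regions are
compositionally real rather than painted onto a continuum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from ._seeds import rng_for
from .assembly import OccurrenceTable
from .errors import ConfigurationError, DataError, InputError
from .predictors import ClimateGrid

__all__ = ["WorldConfig", "SyntheticWorld", "make_world", "degrade_sampling", "write_world"]

_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a synthetic world.

    ``niche_width`` is the standard deviation of each species' Gaussian
    response, in units of the dominant (north-south) gradient's range.
    ``detectability`` is the per-pixel probability that an occupied pixel
    yields a record under unit survey effort; ``effort_zones`` lists
    (pixel-set, multiplier >= 1) pairs marking intensively surveyed areas.
    """

    n_rows: int = 10
    n_cols: int = 20
    n_regions: int = 3
    n_species: int = 80
    niche_width: float = 0.1
    detectability: float = 0.7
    effort_zones: Tuple[Tuple[frozenset, float], ...] = ()
    seed: int = 0
    gradient_ranges: Tuple[float, float] = (1.0, 0.1)
    noise_sd: float = 0.04  # fraction of each gradient's range
    region_weights: Tuple[float, float] = (1.0, 0.0)
    optimum_jitter: float = 0.02  # sd of niche optima around their pool's
    # regional climate centroid, as a fraction of each gradient's range
    ramp_width: float = 0.02  # width of the climatic-belt transitions, in
    # units of the north-south axis (small = sharp zonation)
    linear_mix: float = 0.05  # residual within-belt slope of the NS profile
    max_region_draws: int = 100

    def __post_init__(self):
        if self.n_rows * self.n_cols < 4:
            raise ConfigurationError("lattice must have at least 4 pixels")
        if self.n_regions < 2:
            raise ConfigurationError("need at least 2 true regions")
        if self.n_regions > self.n_rows:
            raise ConfigurationError("cannot fit more latitudinal regions than rows")
        if self.n_species < 1:
            raise ConfigurationError("need at least 1 species")
        if not self.niche_width > 0:
            raise ConfigurationError("niche_width must be positive")
        if not (0 < self.detectability <= 1):
            raise ConfigurationError("detectability must be in (0, 1]")
        zones = tuple((frozenset(z), float(m)) for z, m in self.effort_zones)
        for _, mult in zones:
            if mult < 1:
                raise ConfigurationError("effort multipliers must be >= 1")
        object.__setattr__(self, "effort_zones", zones)


@dataclass
class SyntheticWorld:
    climate: ClimateGrid
    true_regions: pd.Series  # pixel -> label in 1..n_regions
    true_occupancy: pd.DataFrame = field(repr=False)  # pixels x species, 0/1
    occurrences: OccurrenceTable
    config: WorldConfig


def _regions_connected(labels: np.ndarray, n_rows: int, n_cols: int) -> bool:
    lattice = labels.reshape(n_rows, n_cols)
    for region in np.unique(lattice):
        _, n_components = ndimage.label(lattice == region, structure=_ROOK)
        if n_components != 1:
            return False
    return True


def _band_labels(score: np.ndarray, base_score: np.ndarray,
                 belt_of_row: np.ndarray, n_regions: int) -> np.ndarray:
    """Bands of the (noisy) score, labelled 1..n_regions.

    Thresholds sit midway between the noise-free mean scores of consecutive
    climatic belts, so a pixel joins the belt whose score level it is
    closest to."""
    centers = np.array([base_score[belt_of_row == r].mean() for r in range(n_regions)])
    thresholds = (centers[:-1] + centers[1:]) / 2.0
    return 1 + np.digitize(score, thresholds)


def _effort_multiplier(config: WorldConfig, pixels: Sequence) -> np.ndarray:
    mult = np.ones(len(pixels))
    index = {p: i for i, p in enumerate(pixels)}
    for zone, m in config.effort_zones:
        for p in zone:
            if p not in index:
                raise InputError(f"effort zone references unknown pixel {p!r}")
            mult[index[p]] = max(mult[index[p]], m)
    return mult


def make_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a world; deterministic given ``config.seed``."""
    n_rows, n_cols = config.n_rows, config.n_cols
    n = n_rows * n_cols
    pixels = list(range(n))
    rows, cols = np.divmod(np.arange(n), n_cols)
    coords = pd.DataFrame({"row": rows, "col": cols}, index=pd.Index(pixels, name="pixel"))

    t_ns = rows / max(n_rows - 1, 1)
    # belt edges snapped midway between adjacent lattice rows so no row sits
    # exactly on a transition ramp
    spacing = 1.0 / max(n_rows - 1, 1)
    edges = [
        (np.floor(i / config.n_regions * (n_rows - 1)) + 0.5) * spacing
        for i in range(1, config.n_regions)
    ]
    if edges:
        stair = sum(expit((t_ns - b) / config.ramp_width) for b in edges) / len(edges)
    else:
        stair = t_ns
    profile = (1 - config.linear_mix) * stair + config.linear_mix * t_ns
    grad_ns = profile * config.gradient_ranges[0]
    grad_ew = cols / max(n_cols - 1, 1) * config.gradient_ranges[1]
    base = np.column_stack([grad_ns, grad_ew])
    weights = np.asarray(config.region_weights, dtype=float)
    base_score = base @ weights
    belt_of_row = np.searchsorted(np.asarray(edges), t_ns) if edges else np.zeros(n, int)

    labels = None
    for attempt in range(config.max_region_draws):
        rng = rng_for(config.seed, "climate", attempt)
        noise = rng.normal(0.0, 1.0, size=base.shape) * (
            config.noise_sd * np.asarray(config.gradient_ranges)
        )
        values = base + noise
        score = values @ weights
        candidate = _band_labels(score, base_score, belt_of_row, config.n_regions)
        if (np.unique(candidate).size == config.n_regions
                and _regions_connected(candidate, n_rows, n_cols)):
            labels = candidate
            break
    if labels is None:
        raise DataError(
            f"could not draw contiguous regions in {config.max_region_draws} attempts; "
            "lower noise_sd or coarsen the lattice"
        )

    climate = ClimateGrid(pixels, coords, ["clim_ns", "clim_ew"], values)
    effort = _effort_multiplier(config, pixels)
    p_detect = np.minimum(1.0, config.detectability * effort)

    sigma = config.niche_width * config.gradient_ranges[0]
    jitter = config.optimum_jitter * np.asarray(config.gradient_ranges)
    centroids = {r: values[labels == r].mean(axis=0) for r in np.unique(labels)}
    region_ids = sorted(centroids)
    species_ids = [f"sp{i:04d}" for i in range(config.n_species)]
    occupancy = np.zeros((n, config.n_species), dtype=np.int8)
    records = []
    for j, sp in enumerate(species_ids):
        rng_s = rng_for(config.seed, "species", j)
        # species are drawn from region-affiliated pools: the niche optimum
        # sits near the climate centroid of one true region
        pool = region_ids[rng_s.integers(len(region_ids))]
        optimum = centroids[pool] + rng_s.normal(0.0, 1.0, size=2) * jitter
        sq_dist = ((values - optimum) ** 2).sum(axis=1)
        response = np.exp(-sq_dist / (2.0 * sigma**2))
        occupied = rng_s.random(n) < response
        occupancy[:, j] = occupied
        detected = occupied & (rng_s.random(n) < p_detect)
        records.extend((sp, pixels[i]) for i in np.nonzero(detected)[0])

    true_occupancy = pd.DataFrame(occupancy, index=pd.Index(pixels, name="pixel"),
                                  columns=species_ids)
    occurrences = OccurrenceTable.from_records(records)
    true_regions = pd.Series(labels, index=pd.Index(pixels, name="pixel"), name="region")
    return SyntheticWorld(climate, true_regions, true_occupancy, occurrences, config)


def degrade_sampling(world: SyntheticWorld, zone: Iterable, multiplier: float,
                     seed: int | None = None) -> OccurrenceTable:
    """Re-run the detection process with boosted effort inside ``zone``.

    In-zone occupied pixels are recorded with probability
    ``min(1, detectability * multiplier)``; out-of-zone pixels keep the base
    detectability. Creates the biased-sampling condition with one or more
    intensively surveyed areas.
    """
    zone = frozenset(zone)
    pixels = world.climate.pixels
    unknown = zone - set(pixels)
    if unknown:
        raise InputError(f"unknown pixel ids in zone: {sorted(unknown)[:5]}")
    if multiplier < 1:
        raise InputError("multiplier must be >= 1")
    seed = world.config.seed if seed is None else seed
    in_zone = np.array([p in zone for p in pixels])
    p_detect = np.where(
        in_zone,
        np.minimum(1.0, world.config.detectability * multiplier),
        world.config.detectability,
    )
    records = []
    occupancy = world.true_occupancy.to_numpy()
    for j, sp in enumerate(world.true_occupancy.columns):
        rng_s = rng_for(seed, "degrade", j)
        detected = (occupancy[:, j] == 1) & (rng_s.random(len(pixels)) < p_detect)
        records.extend((sp, pixels[i]) for i in np.nonzero(detected)[0])
    return OccurrenceTable.from_records(records)


def write_world(world: SyntheticWorld, outdir: str | Path) -> dict:
    """Write occurrences/grid/climate/truth CSVs; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrences": outdir / "occurrences.csv",
        "grid": outdir / "grid.csv",
        "climate": outdir / "climate.csv",
        "truth": outdir / "truth.csv",
    }
    world.occurrences.to_csv(paths["occurrences"])
    world.climate.coords.reset_index().to_csv(paths["grid"], index=False)
    world.climate.frame().reset_index().to_csv(paths["climate"], index=False)
    world.true_regions.reset_index().to_csv(paths["truth"], index=False)
    return paths
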