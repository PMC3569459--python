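"""End-to-end orchestration of the regionalization pipeline.

One run executes, per subsampling scheme: record dedup -> zone subsampling ->
species filtering (> min_occ occupied pixels) -> per-species replicated AUC
evaluation -> AUC filtering -> final fits, thresholding and binary maps ->
stacking -> richness pixel filter -> Hellinger transform -> v-fold
cross-validated choice of k (per disparity threshold) -> multi-restart
k-means -> spatial/agreement scoring and indicator species. Everything is
deterministic under the master seed: each stage draws from a named RNG
substream derived from it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._seeds import rng_for
from .assembly import (AssemblageMatrix, OccurrenceTable, SubsamplingScheme,
                       filter_pixels, stack, subsample_zone)
from .errors import ConfigurationError, InputError
from .evaluate import (agreement_report, build_adjacency, confusion,
                       cross_scheme_overlap, morans_i_categorical)
from .indicators import affinity_spectrum, indval, top_indicators
from .predictors import ClimateGrid, prune_correlated, read_climate
from .regionalize import hellinger_transform, kmeans, vfold_select_k
from .sdm import (binarize, build_features, evaluate_replicates, filter_by_auc,
                  filter_species, fit_maxent, predict, threshold_max_ss)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and settings of one pipeline run.

    ``occurrences``/``climate`` may be file paths (CSV as written by the
    synthetic module) or in-memory objects; ``grid`` is the coordinate CSV
    when ``climate`` is a path. ``reference`` (pixel -> named region) and
    ``affinity`` (species -> affinity class) are optional.
    """

    occurrences: object
    climate: object
    grid: object = None
    reference: object = None
    affinity: Mapping | None = None
    schemes: Sequence[float] = (1.0, 0.6, 0.4, 0.2)
    zone: Sequence = ()
    k_grid: Sequence[int] = tuple(range(2, 26))
    restarts: int = 100
    cv_restarts: int = 10
    v: int = 50
    disparities: Sequence[float] = (0.03, 0.05)
    beta: float = 2.0
    min_occ: int = 10
    min_auc: float = 0.70
    min_richness: int = 25
    n_reps: int = 10
    r_threshold: float = 0.8
    n_permutations: int = 999
    top_n: int = 20
    max_iter: int = 500
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        for frac in self.schemes:
            if not (0 < frac <= 1):
                raise ConfigurationError(f"invalid subsampling fraction {frac}")
        for d in self.disparities:
            if not (0 < d):
                raise ConfigurationError(f"invalid disparity {d}")
        if min(self.k_grid) < 2:
            raise ConfigurationError("k grid must start at 2 or above")


def _load_inputs(config: PipelineConfig):
    occ = config.occurrences
    if isinstance(occ, (str, Path)):
        if not Path(occ).exists():
            raise ConfigurationError(f"occurrence file not found: {occ}")
        occ = OccurrenceTable.from_csv(occ)
    clim = config.climate
    if isinstance(clim, (str, Path)):
        if not Path(clim).exists():
            raise ConfigurationError(f"climate file not found: {clim}")
        if config.grid is None or not Path(config.grid).exists():
            raise ConfigurationError(f"grid file not found: {config.grid}")
        clim = read_climate(clim, config.grid)
    if not isinstance(clim, ClimateGrid):
        raise ConfigurationError("climate input must be a path or ClimateGrid")
    ref = config.reference
    if isinstance(ref, (str, Path)):
        if not Path(ref).exists():
            raise ConfigurationError(f"reference file not found: {ref}")
        df = pd.read_csv(ref)
        ref = df.set_index(df.columns[0])[df.columns[1]]
    elif isinstance(ref, Mapping):
        ref = pd.Series(dict(ref))
    aff = config.affinity
    if isinstance(aff, (str, Path)):
        if not Path(aff).exists():
            raise ConfigurationError(f"affinity file not found: {aff}")
        df = pd.read_csv(aff)
        aff = dict(zip(df[df.columns[0]], df[df.columns[1]]))
    return occ, clim, ref, aff


def _fit_scheme_models(table: OccurrenceTable, features, feature_names,
                       pixel_index: Mapping, config: PipelineConfig,
                       scheme_label: str):
    """Species filters, replicate AUC evaluation, final fits and binary maps."""
    candidates = filter_species(table, config.min_occ)
    models = []
    for sp in candidates:
        pres_pixels = table.pixels_of(sp)
        try:
            pres_idx = [pixel_index[p] for p in pres_pixels]
        except KeyError as exc:
            raise InputError(f"occurrence pixel {exc.args[0]!r} not in climate grid")
        sp_seed = int(rng_for(config.seed, "sdm", scheme_label, sp).integers(2**31))
        model = fit_maxent(pres_idx, features, beta=config.beta,
                           max_iter=config.max_iter, tol=config.tol,
                           feature_names=feature_names, species=sp)
        model.auc_mean, model.auc_replicates = evaluate_replicates(
            pres_idx, features, beta=config.beta, n_reps=config.n_reps,
            seed=sp_seed, max_iter=config.max_iter, tol=config.tol)
        model._presence_idx = pres_idx
        models.append(model)
    retained = filter_by_auc(models, config.min_auc)
    binary_maps = []
    for model in retained:
        suitability = model.estimator.predict_suitability(features)
        model.threshold = threshold_max_ss(
            suitability[model._presence_idx], suitability)
        smap = predict(model, features, pixels=list(pixel_index))
        binary_maps.append(binarize(smap, model.threshold))
    return candidates, models, retained, binary_maps


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full batch (schemes x disparities); returns the run report.

    When ``outdir`` is given, intermediate artifacts (assemblage matrices,
    region CSVs) and the report JSON are written there.
    """
    t0 = time.time()
    occ, clim, reference, affinity = _load_inputs(config)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    kept_vars, dropped_vars, _ = prune_correlated(clim, config.r_threshold)
    grid = clim.subset_variables(kept_vars)
    features, feature_names, _ = build_features(grid)
    pixel_index = {p: i for i, p in enumerate(grid.pixels)}
    logger.info("predictors: kept %d vars, dropped %d", len(kept_vars), len(dropped_vars))

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "predictors": {"kept": kept_vars, "dropped": dropped_vars},
        "schemes": {},
    }
    assignments: dict = {}

    for frac in config.schemes:
        label = f"s{int(round(frac * 100))}"
        sub_seed = int(rng_for(config.seed, "scheme", label).integers(2**31))
        table = occ
        if config.zone and frac < 1.0:
            table = subsample_zone(
                occ, SubsamplingScheme(frozenset(config.zone), frac, sub_seed))
        candidates, models, retained, binary_maps = _fit_scheme_models(
            table, features, feature_names, pixel_index, config, label)
        logger.info("scheme %s: %d candidate species, %d retained after AUC",
                    label, len(candidates), len(retained))
        matrix = stack(binary_maps, grid.pixels)
        kept_matrix, discarded = filter_pixels(matrix, config.min_richness)
        if outdir is not None:
            kept_matrix.to_csv(outdir / f"assemblage_{label}.csv")
        transformed = hellinger_transform(kept_matrix)
        cv_seed = int(rng_for(config.seed, "cv", label).integers(2**31))
        cv = vfold_select_k(transformed, k_grid=config.k_grid, v=config.v,
                            disparity=min(config.disparities), seed=cv_seed,
                            n_restarts=config.cv_restarts)
        adjacency = build_adjacency(clim.coords.loc[kept_matrix.pixels])
        scheme_entry = {
            "n_records": len(table),
            "n_candidate_species": len(candidates),
            "n_dropped_auc": len(models) - len(retained),
            "n_species_stacked": len(retained),
            "n_pixels_kept": len(kept_matrix.pixels),
            "n_pixels_discarded": len(discarded),
            "cv_error": {str(k): v for k, v in cv.cv_error.items()},
            "disparities": {},
        }
        for disparity in config.disparities:
            chosen = _choose_k(cv.cv_error, sorted(config.k_grid), disparity)
            km_seed = int(rng_for(config.seed, "kmeans", label).integers(2**31))
            assignment = kmeans(transformed, chosen, n_restarts=config.restarts,
                                seed=km_seed, pixels=kept_matrix.pixels, scheme=label)
            moran_seed = int(rng_for(config.seed, "moran", label, str(disparity))
                             .integers(2**31))
            stats = morans_i_categorical(assignment, adjacency,
                                         n_permutations=config.n_permutations,
                                         seed=moran_seed)
            entry = {
                "chosen_k": chosen,
                "sse": assignment.sse,
                "morans_i": stats.morans_i,
                "morans_p": stats.p_value,
            }
            if reference is not None:
                table_ref = confusion(assignment, reference)
                agr = agreement_report(table_ref)
                entry["kappa"] = agr.global_kappa
                entry["overlap_percent"] = {str(c): v for c, v in agr.overlap_percent.items()}
                entry["kappa_per_region"] = {str(c): v for c, v in agr.per_category_kappa.items()}
                entry["agreement_labels"] = {str(c): v for c, v in agr.labels.items()}
            ind_table = indval(kept_matrix, assignment)
            tops = {r: top_indicators(ind_table, r, config.top_n)
                    for r in sorted(assignment.labels.unique())}
            entry["top_indicators"] = {
                str(r): df[["species", "indval"]].to_dict("records")
                for r, df in tops.items()
            }
            if affinity is not None:
                entry["affinity_spectrum"] = {
                    str(r): spec for r, spec in affinity_spectrum(tops, affinity).items()
                }
            if outdir is not None:
                assignment.labels.reset_index().to_csv(
                    outdir / f"regions_{label}_d{int(round(disparity * 100))}.csv",
                    index=False)
            scheme_entry["disparities"][_dkey(disparity)] = entry
            assignments[(label, disparity)] = assignment
        report["schemes"][label] = scheme_entry

    if len(config.schemes) > 1:
        report["cross_scheme_overlap"] = {}
        for disparity in config.disparities:
            labels = [f"s{int(round(f * 100))}" for f in config.schemes]
            pairs = {}
            for i, la in enumerate(labels):
                for lb in labels[i + 1:]:
                    pairs[f"{la}|{lb}"] = cross_scheme_overlap(
                        assignments[(la, disparity)], assignments[(lb, disparity)])
            entry = {"pairwise": pairs}
            if pairs:
                entry["mean"] = float(np.mean(list(pairs.values())))
            report["cross_scheme_overlap"][_dkey(disparity)] = entry

    report["runtime_seconds"] = round(time.time() - t0, 2)
    if outdir is not None:
        with open(outdir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return _jsonable(report)


def _dkey(disparity: float) -> str:
    return f"disparity_{disparity:g}"


def _choose_k(cv_error: Mapping[int, float], k_grid: Sequence[int],
              disparity: float) -> int:
    for i, k in enumerate(k_grid[:-1]):
        err = cv_error[k]
        if err <= 0:
            return k
        if (err - cv_error[k_grid[i + 1]]) / err < disparity:
            return k
    return k_grid[-1]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
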