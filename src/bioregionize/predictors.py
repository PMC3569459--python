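"""Per-pixel environmental predictors.

The analysis grid is a coarse regular lattice (typically ~100x100 km
cells). Fine-resolution climate values are averaged over each
analysis pixel, and collinear predictors are pruned with a Pearson-|r|
threshold before any suitability model sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InputError

__all__ = ["ClimateGrid", "aggregate_climate", "prune_correlated", "read_climate"]


@dataclass
class ClimateGrid:
    """Per-pixel environmental predictor vectors on a lattice.

    Parameters
    ----------
    pixels : ordered pixel ids.
    coords : DataFrame indexed by pixel with integer ``row``/``col`` columns.
    variables : ordered predictor names.
    values : (n_pixels, n_variables) float array, finite.
    """

    pixels: list
    coords: pd.DataFrame
    variables: list
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.pixels = list(self.pixels)
        self.variables = list(self.variables)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.pixels)) != len(self.pixels):
            raise InputError("duplicate pixel ids in climate grid")
        missing = [p for p in self.pixels if p not in self.coords.index]
        if missing:
            raise InputError(f"pixels without coordinates: {missing[:5]}")
        if self.values.shape != (len(self.pixels), len(self.variables)):
            raise InputError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.pixels)} pixels x {len(self.variables)} variables"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite values in climate grid")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.pixels, name="pixel"),
                            columns=self.variables)

    def subset_variables(self, keep: Sequence) -> "ClimateGrid":
        idx = [self.variables.index(v) for v in keep]
        return ClimateGrid(self.pixels, self.coords, list(keep), self.values[:, idx])


def aggregate_climate(
    fine_values: pd.DataFrame,
    cell_to_pixel: Mapping,
    coords: pd.DataFrame | Mapping | None = None,
) -> ClimateGrid:
    """Average fine-resolution cells over each analysis pixel.

    ``fine_values`` is a cells x variables frame (NaN marks a missing cell);
    each pixel's value is the arithmetic mean of its available cells. A pixel
    whose cells are all missing for some variable is a data error.

    ``coords`` maps pixel -> (row, col); when omitted, pixels are laid out on
    a single row (useful for purely aspatial tests).
    """
    mapping = pd.Series(dict(cell_to_pixel))
    if mapping.empty:
        raise InputError("empty cell-to-pixel mapping")
    unknown = [c for c in mapping.index if c not in fine_values.index]
    if unknown:
        raise InputError(f"cells without fine values: {unknown[:5]}")
    grouped = fine_values.loc[mapping.index].groupby(mapping.values).mean()
    for pixel in grouped.index:
        for var in grouped.columns:
            if pd.isna(grouped.loc[pixel, var]):
                raise DataError(
                    f"pixel {pixel!r} has no non-missing cells for variable {var!r}"
                )
    pixels = list(grouped.index)
    if coords is None:
        coords = pd.DataFrame({"row": 0, "col": range(len(pixels))},
                              index=pd.Index(pixels, name="pixel"))
    elif not isinstance(coords, pd.DataFrame):
        coords = pd.DataFrame(
            [(p, r, c) for p, (r, c) in dict(coords).items()],
            columns=["pixel", "row", "col"],
        ).set_index("pixel")
    return ClimateGrid(pixels, coords, list(grouped.columns), grouped.to_numpy())


def prune_correlated(grid: ClimateGrid, r_threshold: float = 0.8):
    """Greedy collinearity pruning at a Pearson-|r| threshold.

    Variables are scanned in grid order; a variable is dropped when its |r|
    with any earlier *kept* variable exceeds ``r_threshold`` (absolute value,
    since strong negative correlation is equally collinear). Returns
    ``(kept, dropped, correlation_matrix)``.
    """
    if grid.n_pixels < 2:
        raise DataError("need at least 2 pixels to compute correlations")
    frame = grid.frame()
    stds = frame.std(ddof=0)
    zero_var = list(stds.index[stds == 0])
    if zero_var:
        raise DataError(f"zero-variance variables: {zero_var}")
    corr = frame.corr(method="pearson")
    kept: list = []
    dropped: list = []
    for var in grid.variables:
        if any(abs(corr.loc[var, k]) > r_threshold for k in kept):
            dropped.append(var)
        else:
            kept.append(var)
    return kept, dropped, corr


def read_climate(climate_csv: str | Path, grid_csv: str | Path) -> ClimateGrid:
    """Read the climate and grid CSVs written by :mod:`bioregionize.synthetic`."""
    clim = pd.read_csv(climate_csv).set_index("pixel")
    coords = pd.read_csv(grid_csv).set_index("pixel")[["row", "col"]]
    return ClimateGrid(list(clim.index), coords, list(clim.columns), clim.to_numpy())
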