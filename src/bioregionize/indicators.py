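"""Indicator species analysis (IndVal) and biogeographic affinity spectra.

For species i and region j, specificity A is the number of pixels of region
j holding the species divided by its total occupied pixels across regions,
fidelity B is the fraction of region-j pixels holding it, and
IndVal = A x B. A perfect indicator (fills its region, absent elsewhere)
scores 1. Values are reported on the 0-1 scale; a x100 option matches the
percent convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly import AssemblageMatrix
from .errors import InputError
from .regionalize import RegionAssignment

__all__ = ["IndicatorTable", "indval", "top_indicators", "affinity_spectrum"]


@dataclass
class IndicatorTable:
    """(species, region) -> (A, B, indval) entries as a tidy frame."""

    entries: pd.DataFrame  # columns: species, region, A, B, indval
    scale100: bool = False

    def frame(self) -> pd.DataFrame:
        if not self.scale100:
            return self.entries
        out = self.entries.copy()
        out["indval"] = out["indval"] * 100.0
        return out


def indval(matrix: AssemblageMatrix, labels, scale100: bool = False) -> IndicatorTable:
    """IndVal for every recorded species x region pair.

    ``labels`` must label every matrix pixel. Species recorded in zero
    pixels are omitted.
    """
    if isinstance(labels, RegionAssignment):
        labels = labels.labels
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    missing = [p for p in matrix.pixels if p not in labels.index]
    if missing:
        raise InputError(f"unlabelled pixels: {missing[:5]}")
    lab = labels.loc[matrix.pixels].to_numpy()
    X = matrix.values.astype(float)
    totals = X.sum(axis=0)  # occupied pixels per species
    regions = np.unique(lab)
    rows = []
    for region in regions:
        in_region = lab == region
        n_region = int(in_region.sum())
        pres_in_region = X[in_region].sum(axis=0)
        for j, sp in enumerate(matrix.species):
            if totals[j] == 0:
                continue
            a = pres_in_region[j] / totals[j]
            b = pres_in_region[j] / n_region
            rows.append((sp, region, a, b, a * b))
    entries = pd.DataFrame(rows, columns=["species", "region", "A", "B", "indval"])
    return IndicatorTable(entries, scale100=scale100)


def top_indicators(table: IndicatorTable, region, n: int = 20) -> pd.DataFrame:
    """The n species with the highest IndVal in a region; ties broken by
    species id ascending."""
    sub = table.entries[table.entries["region"] == region]
    if sub.empty:
        raise InputError(f"region {region!r} not present in indicator table")
    ranked = sub.sort_values(["indval", "species"], ascending=[False, True],
                             kind="stable")
    return ranked.head(n).reset_index(drop=True)


def affinity_spectrum(top_lists: Mapping, affinity: Mapping) -> dict:
    """Per-region proportions of biogeographic affinity classes among the
    indicator species; species without a lookup entry count as "unknown"."""
    spectrum: dict = {}
    for region, species_list in top_lists.items():
        if isinstance(species_list, pd.DataFrame):
            species_list = species_list["species"].tolist()
        if len(species_list) == 0:
            spectrum[region] = {}
            continue
        counts: dict = {}
        for sp in species_list:
            cls = affinity.get(sp, "unknown")
            counts[cls] = counts.get(cls, 0) + 1
        total = sum(counts.values())
        spectrum[region] = {cls: c / total for cls, c in counts.items()}
    return spectrum
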