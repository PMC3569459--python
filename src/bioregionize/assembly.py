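"""Occurrence handling and assemblage construction.

Covers the record-level hygiene (one presence per species x pixel), the
zone-restricted random subsampling used to soften survey-intensity bias,
stacking of per-species binary prediction maps into a pixels x species
assemblage matrix, and the minimum-richness pixel filter applied before
clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import rng_for
from .errors import InputError

__all__ = [
    "OccurrenceTable",
    "AssemblageMatrix",
    "SubsamplingScheme",
    "dedupe",
    "subsample_zone",
    "stack",
    "filter_pixels",
]


@dataclass
class OccurrenceTable:
    """Deduplicated (species, pixel) presence records with set semantics."""

    records: pd.DataFrame  # columns: species, pixel; unique rows, sorted

    def __post_init__(self):
        df = self.records
        if list(df.columns) != ["species", "pixel"]:
            raise InputError("occurrence records must have columns species,pixel")
        self.records = (
            df.drop_duplicates().sort_values(["species", "pixel"]).reset_index(drop=True)
        )

    @classmethod
    def from_records(cls, pairs: Iterable[tuple]) -> "OccurrenceTable":
        pairs = list(pairs)
        for lineno, rec in enumerate(pairs, start=1):
            if not (isinstance(rec, (tuple, list)) and len(rec) == 2):
                raise InputError(f"malformed occurrence record at line {lineno}: {rec!r}")
        return cls(pd.DataFrame(pairs, columns=["species", "pixel"]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceTable":
        df = pd.read_csv(path)
        if list(df.columns) != ["species", "pixel"]:
            raise InputError(f"{path}: expected header species,pixel, got {list(df.columns)}")
        bad = df.index[df.isna().any(axis=1)]
        if len(bad):
            raise InputError(f"{path}: malformed record at line {bad[0] + 2}")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, OccurrenceTable) and self.records.equals(other.records)

    def species(self) -> list:
        return sorted(self.records["species"].unique().tolist())

    def occupancy_counts(self) -> pd.Series:
        """Occupied-pixel count per species."""
        return self.records.groupby("species")["pixel"].nunique()

    def pixels_of(self, species) -> list:
        return sorted(self.records.loc[self.records["species"] == species, "pixel"].tolist())


def dedupe(raw_records: Iterable[tuple] | pd.DataFrame) -> OccurrenceTable:
    """Collapse repeated reports of a species in a pixel to a single presence."""
    if isinstance(raw_records, pd.DataFrame):
        return OccurrenceTable(raw_records)
    return OccurrenceTable.from_records(raw_records)


@dataclass(frozen=True)
class SubsamplingScheme:
    """Retain ``fraction`` of the pooled records inside ``zone``; seeded."""

    zone: frozenset
    fraction: float
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fraction <= 1.0):
            raise InputError(f"fraction must be in (0, 1], got {self.fraction}")
        object.__setattr__(self, "zone", frozenset(self.zone))


def subsample_zone(table: OccurrenceTable, scheme: SubsamplingScheme) -> OccurrenceTable:
    """Randomly retain ``round(fraction * n_zone)`` in-zone records (pooled
    across species, without replacement); out-of-zone records are untouched.
    """
    df = table.records
    in_zone = df["pixel"].isin(scheme.zone)
    zone_df = df[in_zone]
    n_zone = len(zone_df)
    n_keep = int(math.floor(scheme.fraction * n_zone + 0.5))  # round half-up
    if n_keep >= n_zone:
        return OccurrenceTable(df.copy())
    rng = rng_for(scheme.seed, "subsample")
    keep_idx = rng.choice(zone_df.index.to_numpy(), size=n_keep, replace=False)
    kept = pd.concat([df[~in_zone], df.loc[np.sort(keep_idx)]])
    return OccurrenceTable(kept.reset_index(drop=True))


@dataclass
class AssemblageMatrix:
    """Pixels x species binary potential-composition matrix."""

    pixels: list
    species: list
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.pixels = list(self.pixels)
        self.species = list(self.species)
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.pixels), len(self.species)):
            raise InputError("assemblage matrix shape mismatch")
        if not np.isin(self.values, (0, 1)).all():
            raise InputError("assemblage matrix must be binary")
        self.values = self.values.astype(np.int8)

    @property
    def richness(self) -> pd.Series:
        return pd.Series(self.values.sum(axis=1), index=self.pixels, name="richness")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.pixels, name="pixel"),
                            columns=self.species)

    def to_csv(self, path: str | Path) -> None:
        self.frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AssemblageMatrix":
        df = pd.read_csv(path).set_index("pixel")
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def to_triplets(self, path: str | Path) -> None:
        rows, cols = np.nonzero(self.values)
        pd.DataFrame({
            "pixel": [self.pixels[i] for i in rows],
            "species": [self.species[j] for j in cols],
            "presence": 1,
        }).to_csv(path, index=False)

    @classmethod
    def from_triplets(cls, path: str | Path, pixels: Sequence, species: Sequence) -> "AssemblageMatrix":
        df = pd.read_csv(path)
        values = np.zeros((len(pixels), len(species)), dtype=np.int8)
        pidx = {p: i for i, p in enumerate(pixels)}
        sidx = {s: j for j, s in enumerate(species)}
        for _, rec in df.iterrows():
            values[pidx[rec["pixel"]], sidx[rec["species"]]] = 1
        return cls(list(pixels), list(species), values)


def stack(binary_maps: Sequence, pixels: Sequence) -> AssemblageMatrix:
    """Stack per-species binary maps into an assemblage matrix.

    Each map must provide ``species`` and a ``presence`` mapping defined for
    every pixel of ``pixels``.
    """
    pixels = list(pixels)
    columns = []
    species = []
    for bmap in binary_maps:
        try:
            col = [int(bmap.presence[p]) for p in pixels]
        except KeyError as exc:
            raise InputError(
                f"binary map for species {bmap.species!r} is missing pixel {exc.args[0]!r}"
            ) from exc
        columns.append(col)
        species.append(bmap.species)
    values = (np.array(columns, dtype=np.int8).T if columns
              else np.zeros((len(pixels), 0), dtype=np.int8))
    return AssemblageMatrix(pixels, species, values)


def filter_pixels(matrix: AssemblageMatrix, min_richness: int = 25):
    """Discard pixels with predicted richness strictly below ``min_richness``.

    Pixels with very few predicted occurrences give a strong, misleading
    signal in k-means, so they are removed before clustering. Returns
    ``(kept_matrix, discarded_pixel_list)``.
    """
    rich = matrix.richness.to_numpy()
    keep = rich >= min_richness
    kept = AssemblageMatrix(
        [p for p, k in zip(matrix.pixels, keep) if k],
        matrix.species,
        matrix.values[keep],
    )
    discarded = [p for p, k in zip(matrix.pixels, keep) if not k]
    return kept, discarded
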