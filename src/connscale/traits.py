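"""Species-level trait tables (volumes in cm³, areas in cm²)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical trait columns and their units
STANDARD_UNITS = {
    "cerebral_volume": "cm3",
    "gray_matter_volume": "cm3",
    "white_matter_volume": "cm3",
    "cortical_surface_area": "cm2",
    "cc_area": "cm2",
}


@dataclass
class TraitTable:
    """One row per species; named quantitative trait columns.

    ``transforms`` records, per column, whether values are raw, log10 or z;
    volumetric/area traits must be strictly positive before a log transform.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    transforms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise ValueError("duplicate species in trait table")
        for col in self.data.columns:
            self.transforms.setdefault(col, "raw")
            self.units.setdefault(col, STANDARD_UNITS.get(col, ""))

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"trait column {name!r} not in table")
        return self.data[name]

    def fold_range(self, name: str) -> float:
        """max/min ratio of a (positive) trait across species."""
        col = self.column(name)
        if (col <= 0).any():
            raise ValueError(f"fold range needs positive values in {name!r}")
        return float(col.max() / col.min())

    def log10(self, columns: list[str] | None = None) -> "TraitTable":
        cols = columns or list(self.data.columns)
        df = self.data.copy()
        transforms = dict(self.transforms)
        for c in cols:
            if transforms.get(c) != "raw":
                raise ValueError(f"column {c!r} already transformed")
            if (df[c] <= 0).any():
                raise ValueError(f"column {c!r} must be positive for log10")
            df[c] = np.log10(df[c])
            transforms[c] = "log10"
        return TraitTable(df, dict(self.units), transforms)

    def restrict(self, species: list[str]) -> "TraitTable":
        missing = set(species) - set(self.data.index)
        if missing:
            raise ValueError(f"species missing from trait table: {sorted(missing)}")
        return TraitTable(self.data.loc[species], dict(self.units), dict(self.transforms))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)
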