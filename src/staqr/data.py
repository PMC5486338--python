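"""Child-level analysis table.

One row per child: hemoglobin concentration (g/dL, altitude-adjusted
upstream), categorical covariates, continuous covariates (child age in
months, mother's age at birth in years, breastfeeding duration in months)
and a district label used as the spatial index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: WHO cut-off below which a child under five is classified anemic (g/dL).
ANEMIA_CUTOFF = 11.0


@dataclass
class ChildDataset:
    """Analysis table plus column-role metadata.

    Parameters
    ----------
    df
        One row per child. Must contain ``hb_col`` and, when
        ``district_col`` is set, that column too.
    hb_col
        Name of the hemoglobin column (g/dL).
    district_col
        Name of the district label column, or ``None`` for purely
        tabular data (e.g. the printed-table fixture).
    categorical, continuous
        Covariate names by role.
    references
        Reference category per categorical covariate, used for dummy
        coding. Covariates absent from this map default to their first
        observed level.
    """

    df: pd.DataFrame
    hb_col: str = "hb"
    district_col: str | None = "district"
    categorical: tuple[str, ...] = ()
    continuous: tuple[str, ...] = ()
    references: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = set(self.df.columns)
        needed = {self.hb_col, *self.categorical, *self.continuous}
        if self.district_col is not None:
            needed.add(self.district_col)
        missing = sorted(needed - cols)
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def hb(self) -> np.ndarray:
        return self.df[self.hb_col].to_numpy(dtype=float)

    @property
    def anemic(self) -> np.ndarray:
        """Boolean anemia flag, Hb strictly below 11 g/dL."""
        return self.hb < ANEMIA_CUTOFF

    def districts(self) -> np.ndarray:
        if self.district_col is None:
            raise ValueError("dataset has no district column")
        return self.df[self.district_col].to_numpy()

    def levels(self, variable: str) -> list:
        """Levels of a categorical variable in order of first appearance."""
        col = self.df[variable].dropna()
        return list(pd.unique(col))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **roles) -> "ChildDataset":
        return cls(pd.read_csv(path), **roles)
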