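"""Feature-table preparation for chromatography/mass-spec style data:
half-minimum imputation, interquartile-range filtering, and standardization.

The table is samples x features; an absent measurement is an explicit
missing marker (NaN in memory, an empty cell in CSV).  The conventional
order is impute -> filter -> standardize, after which no missing values
remain and every retained feature has mean 0 and unit (n-1) variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "half_min_impute", "iqr_filter", "standardize", "prepare_table"]


@dataclass
class FeatureTable:
    """Samples-by-features grid with explicit missing entries.

    Thin wrapper over a DataFrame (rows = samples, columns = features)
    enforcing unique ids and non-negative observed values on ingest.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("sample and feature ids must be unique")
        self.values = df.astype(float)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path)


def half_min_impute(table: FeatureTable) -> FeatureTable:
    """Replace each absent entry by half the feature's minimum present value."""
    df = table.values
    all_absent = df.columns[df.isna().all(axis=0)]
    if len(all_absent):
        raise ValueError(f"feature(s) with no present values: {list(all_absent)}")
    fill = 0.5 * df.min(axis=0, skipna=True)
    return FeatureTable(df.fillna(fill))


def iqr_filter(table: FeatureTable, min_iqr: float) -> FeatureTable:
    """Drop features whose interquartile range falls below *min_iqr*.

    Quartiles use the linear-interpolation convention; the sample axis is
    never touched.
    """
    if min_iqr < 0:
        raise ValueError("min_iqr must be non-negative")
    df = table.values
    q1 = df.quantile(0.25, interpolation="linear")
    q3 = df.quantile(0.75, interpolation="linear")
    keep = (q3 - q1) >= min_iqr
    return FeatureTable(df.loc[:, keep])


def standardize(table: FeatureTable) -> FeatureTable:
    """Scale every feature to mean 0 and unit standard deviation (n-1)."""
    df = table.values
    sd = df.std(axis=0, ddof=1)
    zero = sd[~(sd > 0)].index
    if len(zero):
        raise ValueError(f"zero-spread feature(s): {list(zero)}")
    return FeatureTable((df - df.mean(axis=0)) / sd)


def prepare_table(table: FeatureTable, min_iqr: float = 0.0) -> FeatureTable:
    """Full chain: half-minimum impute, IQR filter, standardize."""
    return standardize(iqr_filter(half_min_impute(table), min_iqr))
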