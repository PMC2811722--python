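"""Core tabular containers for quantified GC/MS peak data.

A :class:`PeakTable` holds the peak-height matrix of one experimental
group at one collection timepoint: rows are individual animals (urine
donors), columns are total-ion-chromatogram peaks identified by opaque
labels such as ``P07``.  Heights are on the linear intensity scale as
quantified from the chromatogram unless a log transform has been applied
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

#: Metadata columns used in the CSV interchange format, in column order.
METADATA_COLUMNS = ("sample_id", "model", "condition", "timepoint")

CONDITIONS = ("tumor", "placebo")
TIMEPOINTS = ("early", "late")


@dataclass(frozen=True)
class GroupLabel:
    """Factor pair identifying a sample's experimental group."""

    model: str
    condition: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DataError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


@dataclass(frozen=True)
class PeakTable:
    """Samples x peaks intensity matrix for one (group, timepoint).

    Parameters
    ----------
    values
        DataFrame indexed by sample identifier with one column per peak.
    model, condition, timepoint
        Group metadata shared by every row of the table.
    """

    values: pd.DataFrame = field(repr=False)
    model: str
    condition: str
    timepoint: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise DataError("peak table must have at least one sample and one peak")
        if v.index.duplicated().any():
            dups = sorted(v.index[v.index.duplicated()].unique())
            raise DataError(f"duplicate sample identifiers: {dups}")
        if v.columns.duplicated().any():
            dups = sorted(v.columns[v.columns.duplicated()].unique())
            raise DataError(f"duplicate peak identifiers: {dups}")
        if self.condition not in CONDITIONS:
            raise DataError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise DataError("peak table contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def label(self) -> GroupLabel:
        return GroupLabel(self.model, self.condition)

    def with_values(self, values: pd.DataFrame) -> "PeakTable":
        """Return a copy of this table carrying new values."""
        return replace(self, values=values)


def peak_ids(n_peaks: int) -> list[str]:
    """Default zero-padded peak identifiers ``P01`` ... ``P<n>``."""
    width = max(2, len(str(n_peaks)))
    return [f"P{i + 1:0{width}d}" for i in range(n_peaks)]
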