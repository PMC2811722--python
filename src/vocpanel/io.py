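"""CSV and YAML interchange.

All tabular artifacts are UTF-8 CSV with a header row and ``.`` decimal
separator.  A peak-table CSV carries the metadata columns
``sample_id, model, condition, timepoint`` followed by one column per
peak; values round-trip at full float64 precision.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .tables import METADATA_COLUMNS, PeakTable


def write_peak_table(table: PeakTable, path) -> None:
    """Write one (group, timepoint) peak table as CSV."""
    df = table.values.copy()
    df.insert(0, "timepoint", table.timepoint)
    df.insert(0, "condition", table.condition)
    df.insert(0, "model", table.model)
    df.index.name = "sample_id"
    df.to_csv(path)


def read_peak_table(path) -> PeakTable:
    """Read a peak-table CSV written by :func:`write_peak_table`.

    The file must describe exactly one (model, condition, timepoint)
    group; missing metadata columns and duplicate identifiers are
    errors.
    """
    # pandas silently mangles duplicate header names; check them raw
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    dup = [c for c, k in Counter(header).items() if k > 1]
    if dup:
        raise DataError(f"{path}: duplicate column identifiers: {sorted(dup)}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise DataError(f"{path}: peak table is empty")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing metadata columns: {missing}")
    meta = df[["model", "condition", "timepoint"]].drop_duplicates()
    if len(meta) != 1:
        raise DataError(
            f"{path}: expected one (model, condition, timepoint) group, "
            f"found {len(meta)}"
        )
    values = df.drop(columns=["model", "condition", "timepoint"]).set_index(
        "sample_id"
    )
    if values.shape[1] == 0:
        raise DataError(f"{path}: no peak columns")
    values.index = values.index.astype(str)
    row = meta.iloc[0]
    return PeakTable(
        values,
        model=str(row["model"]),
        condition=str(row["condition"]),
        timepoint=str(row["timepoint"]),
    )


def write_tic(tic, path) -> None:
    """Write one trace as a two-column (rt, intensity) CSV."""
    pd.DataFrame({"rt": tic.rt, "intensity": tic.intensity}).to_csv(path, index=False)


def read_tic(path):
    from .chromatogram import TIC

    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("rt", "intensity"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    return TIC(rt=df["rt"].to_numpy(), intensity=df["intensity"].to_numpy())


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, classifier settings and seeds for a pipeline run."""

    seed: int = 0
    n_per_group: int = 25
    n_peaks: int = 47
    screen_alpha: float = 1e-4
    screen_test: str = "welch"
    anova_loose: float = 0.05
    anova_strict: float = 0.002
    sigma: float = 0.9
    C: float = 1.0
    cv_k: int = 10
    holdout_train: int = 13
    holdout_test: int = 12
    max_candidates: int = 11
    paper_mode: bool = False
    pca_components: int = 2
    protocols: tuple[str, ...] = ("cv10", "holdout", "transfer")
    effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("screen_alpha", "anova_loose", "anova_strict"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.cv_k < 2:
            raise ConfigError("cv_k must be at least 2")
        if self.sigma <= 0 or self.C <= 0:
            raise ConfigError("sigma and C must be strictly positive")
        unknown = set(self.protocols) - {"cv10", "holdout", "transfer"}
        if unknown:
            raise ConfigError(f"unknown protocols: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        if "protocols" in raw:
            raw["protocols"] = tuple(raw["protocols"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from None

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["protocols"] = list(d["protocols"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
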