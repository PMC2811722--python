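"""Total-ion-chromatogram preprocessing.

Turns raw TIC traces into a peak table that is consistent across
samples: peaks are detected once, on the point-wise mean trace of all
samples, so every animal is quantified over the same retention-time
windows.  Heights are the window maxima; the table is then
log-transformed and row-centred to remove overall intensity differences
between urine samples (loading, dilution, fibre efficiency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import DataError
from .tables import PeakTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TIC:
    """One total-ion chromatogram: intensity versus retention time.

    ``rt`` is in minutes and must be strictly increasing; ``intensity``
    has the same length.
    """

    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "intensity", inten)
        if rt.ndim != 1 or rt.size == 0:
            raise DataError("retention-time grid must be a non-empty 1-D array")
        if inten.shape != rt.shape:
            raise DataError(
                f"length mismatch: {rt.size} retention times vs "
                f"{inten.size} intensities"
            )
        if not np.all(np.diff(rt) > 0):
            raise DataError("retention-time grid must be strictly increasing")

    def __len__(self) -> int:
        return self.rt.size


@dataclass(frozen=True)
class PeakWindow:
    """Half-open retention-time interval ``[start, end)`` for one peak."""

    window_id: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(
                f"window {self.window_id}: start {self.start} must be < end {self.end}"
            )


def _common_grid(tics: Sequence[TIC]) -> np.ndarray:
    grid = tics[0].rt
    for t in tics[1:]:
        if t.rt.shape != grid.shape or not np.array_equal(t.rt, grid):
            raise DataError(
                "all TICs must share an identical retention-time grid; "
                "resample before window detection"
            )
    return grid


def detect_windows(
    tics: Iterable[TIC],
    min_prominence: float = 0.01,
    min_separation: float = 0.5,
) -> list[PeakWindow]:
    """Detect peak windows shared by all samples.

    Local maxima of the point-wise mean trace whose prominence is at
    least ``min_prominence`` times the mean-trace maximum become window
    centres.  Adjacent windows meet at the midpoint between their
    centres, and no window extends further than ``min_separation``
    minutes from its centre.  Detection is fully deterministic.

    Parameters
    ----------
    tics
        One or more traces on a common retention-time grid.
    min_prominence
        Prominence threshold as a fraction of the mean-trace maximum.
    min_separation
        Minimum centre-to-centre distance, in minutes; also the maximum
        half-width of a window.
    """
    tics = list(tics)
    if not tics:
        raise DataError("window detection requires at least one TIC")
    grid = _common_grid(tics)
    mean_trace = np.mean([t.intensity for t in tics], axis=0)
    top = float(mean_trace.max())
    if top <= 0:
        return []
    # translate the separation into a grid-point distance (>= 1)
    step = float(np.median(np.diff(grid)))
    distance = max(1, int(round(min_separation / step)))
    centers, _ = find_peaks(
        mean_trace, prominence=min_prominence * top, distance=distance
    )
    if centers.size == 0:
        return []
    ct = grid[centers]
    windows: list[PeakWindow] = []
    width = max(2, len(str(ct.size)))
    for i, c in enumerate(ct):
        lo = grid[0] if i == 0 else 0.5 * (ct[i - 1] + c)
        hi = grid[-1] + step if i == ct.size - 1 else 0.5 * (c + ct[i + 1])
        lo = max(lo, c - min_separation)
        hi = min(hi, c + min_separation)
        windows.append(PeakWindow(f"W{i + 1:0{width}d}", float(lo), float(hi)))
    return windows


def quantify(tic: TIC, windows: Sequence[PeakWindow]) -> np.ndarray:
    """Peak heights: maximum intensity inside each half-open window.

    A window containing no grid point yields height 0 with a warning.
    """
    heights = np.zeros(len(windows))
    for i, w in enumerate(windows):
        mask = (tic.rt >= w.start) & (tic.rt < w.end)
        if not mask.any():
            logger.warning(
                "window %s [%g, %g) contains no grid points; height set to 0",
                w.window_id,
                w.start,
                w.end,
            )
            continue
        heights[i] = float(tic.intensity[mask].max())
    return heights


def quantify_samples(
    tics: Mapping[str, TIC],
    windows: Sequence[PeakWindow],
    model: str,
    condition: str,
    timepoint: str,
) -> PeakTable:
    """Quantify a collection of per-sample traces into one PeakTable."""
    if not tics:
        raise DataError("no TICs to quantify")
    rows = {sid: quantify(t, windows) for sid, t in tics.items()}
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=[w.window_id for w in windows]
    )
    return PeakTable(values, model=model, condition=condition, timepoint=timepoint)


def log_transform(table: PeakTable, offset: float = 1.0) -> PeakTable:
    """Natural-log transform, ``v -> ln(v + offset)``.

    The default offset of 1 keeps zero heights finite and maps them to 0.
    """
    v = table.values.to_numpy(dtype=float)
    if np.any(v + offset <= 0):
        raise DataError(f"log transform undefined: values + offset ({offset}) <= 0")
    out = pd.DataFrame(
        np.log(v + offset), index=table.values.index, columns=table.values.columns
    )
    return table.with_values(out)


def normalize_intensity(table: PeakTable) -> PeakTable:
    """Centre each sample row by its own mean (log-scale total-intensity
    correction); output rows have mean 0.

    Idempotent, and invariant to adding a per-sample constant — the
    point of the correction: overall loading differences between urine
    samples cancel.
    """
    v = table.values
    out = v.sub(v.mean(axis=1), axis=0)
    return table.with_values(out)
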