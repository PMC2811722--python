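"""Term-effect subtraction and univariate peak screening.

Every animal contributes urine at an early (pre-tumor) and a terminal
stage.  Changes common to tumor and placebo animals over that span —
ageing, housing, season: the "term effect" — are removed by the
per-animal difference ``R_i = tH_i - eH_i`` between the late and early
peak heights.  For placebo animals ``R_i`` is pure term effect; for
tumor animals it is term plus tumor effect, so the tumor effect is what
remains after comparing the two groups.

``R`` is z-scored per peak over the pooled analysis set of one model,
then screened peak-by-peak with a two-sided two-sample test at a raw
(uncorrected) significance threshold, by default 1e-4.  No
multiple-testing correction is applied; the threshold is deliberately
strict instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .tables import PeakTable

logger = logging.getLogger(__name__)

#: Univariate tests supported by :func:`screen_peaks`.
SCREEN_TESTS = ("welch", "pooled", "wilcoxon")


@dataclass(frozen=True)
class SubtractedMatrix:
    """Per-animal, per-peak term-effect-subtracted values.

    ``values`` is samples x peaks; ``labels`` carries the (model,
    condition) factor pair per sample.  ``normalized`` records whether
    peak columns have been z-scored over the pooled sample set.
    """

    values: pd.DataFrame = field(repr=False)
    labels: pd.DataFrame = field(repr=False)
    normalized: bool = False
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise DataError("values and labels must be indexed by the same samples")
        missing = {"model", "condition"} - set(self.labels.columns)
        if missing:
            raise DataError(f"labels missing columns: {sorted(missing)}")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.values.columns)


def _stage_maximum(stage: Union[PeakTable, Sequence[PeakTable]]) -> PeakTable:
    """Collapse multiple collections of one stage to per-sample maxima."""
    if isinstance(stage, PeakTable):
        return stage
    tabs = list(stage)
    if not tabs:
        raise DataError("a stage needs at least one collection")
    first = tabs[0]
    out = first.values
    for t in tabs[1:]:
        _check_aligned(first, t)
        out = np.maximum(out, t.values)
    return first.with_values(out)


def _check_aligned(a: PeakTable, b: PeakTable) -> None:
    if list(a.values.index) != list(b.values.index):
        extra = sorted(set(a.values.index) ^ set(b.values.index))
        raise DataError(f"sample identifiers differ between stages: {extra or 'order'}")
    if list(a.values.columns) != list(b.values.columns):
        extra = sorted(set(a.values.columns) ^ set(b.values.columns))
        raise DataError(f"peak identifiers differ between stages: {extra or 'order'}")


def subtract_term_effect(
    early: Union[PeakTable, Sequence[PeakTable]],
    late: Union[PeakTable, Sequence[PeakTable]],
) -> SubtractedMatrix:
    """``R[s, p] = late[s, p] - early[s, p]`` for one group.

    If a stage comprises several collections, each cell is first the
    per-sample maximum across that stage's collections.
    """
    e = _stage_maximum(early)
    t = _stage_maximum(late)
    _check_aligned(e, t)
    values = t.values - e.values
    labels = pd.DataFrame(
        {"model": e.model, "condition": e.condition}, index=values.index
    )
    return SubtractedMatrix(
        values=values,
        labels=labels,
        normalized=False,
        provenance=(
            f"{e.model}/{e.condition}/{e.timepoint}",
            f"{t.model}/{t.condition}/{t.timepoint}",
        ),
    )


def combine(matrices: Sequence[SubtractedMatrix]) -> SubtractedMatrix:
    """Stack the subtracted matrices of several groups into one analysis set."""
    mats = list(matrices)
    if not mats:
        raise DataError("nothing to combine")
    cols = mats[0].peak_ids
    for m in mats[1:]:
        if m.peak_ids != cols:
            raise DataError("cannot combine matrices with different peak identifiers")
    return SubtractedMatrix(
        values=pd.concat([m.values for m in mats]),
        labels=pd.concat([m.labels for m in mats]),
        normalized=all(m.normalized for m in mats) and len(mats) == 1,
        provenance=tuple(p for m in mats for p in m.provenance),
    )


def normalize_subtracted(R: SubtractedMatrix) -> SubtractedMatrix:
    """Z-score each peak column over all pooled samples (population SD).

    Zero-variance columns become all zeros with a warning.  Idempotent.
    """
    v = R.values.to_numpy(dtype=float)
    mean = v.mean(axis=0)
    sd = v.std(axis=0)  # population SD
    flat = sd == 0
    if flat.any():
        logger.warning(
            "zero-variance peak columns set to 0: %s",
            list(np.asarray(R.peak_ids)[flat]),
        )
    sd = np.where(flat, 1.0, sd)
    out = (v - mean) / sd
    out[:, flat] = 0.0
    values = pd.DataFrame(out, index=R.values.index, columns=R.values.columns)
    return replace(R, values=values, normalized=True)


def screen_peaks(
    R: SubtractedMatrix,
    alpha: float = 1e-4,
    test: str = "welch",
) -> tuple[list[str], pd.DataFrame]:
    """Per-peak two-sided tumor-vs-placebo test on subtracted values.

    Parameters
    ----------
    R
        Analysis set containing exactly the two conditions of one model.
    alpha
        Raw significance threshold (default 1e-4; no multiplicity
        correction — see module docstring).
    test
        ``welch`` (default; unequal-variance t), ``pooled`` (classic t),
        or ``wilcoxon`` (rank-sum).

    Returns
    -------
    selected
        Peaks with p < alpha, sorted by ascending p.
    report
        One row per peak: class means, statistic, p-value, selected flag,
        sorted by ascending p.
    """
    if test not in SCREEN_TESTS:
        raise DataError(f"unknown test {test!r}; choose from {SCREEN_TESTS}")
    cond = R.labels["condition"]
    classes = sorted(cond.unique())
    if classes != ["placebo", "tumor"]:
        raise DataError(
            f"screening needs exactly the conditions tumor and placebo, got {classes}"
        )
    if R.labels["model"].nunique() != 1:
        raise DataError("screening is per model; combine one model's groups only")
    a = R.values.loc[cond == "tumor"].to_numpy(dtype=float)
    b = R.values.loc[cond == "placebo"].to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise DataError("each condition needs at least 2 samples")
    if test == "welch":
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    elif test == "pooled":
        res = stats.ttest_ind(a, b, axis=0, equal_var=True)
    else:
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    stat = np.asarray(res.statistic, dtype=float)
    pval = np.asarray(res.pvalue, dtype=float)
    report = pd.DataFrame(
        {
            "peak": R.peak_ids,
            "mean_tumor": a.mean(axis=0),
            "mean_placebo": b.mean(axis=0),
            "statistic": stat,
            "p_value": pval,
            "selected": pval < alpha,
        }
    ).sort_values(["p_value", "peak"], kind="stable", ignore_index=True)
    selected = report.loc[report["selected"], "peak"].tolist()
    return selected, report
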