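"""Balanced two-factor ANOVA with interaction, per peak.

Each peak's normalized subtracted value is decomposed as

    y_ijk = mu + a_i + b_j + (ab)_ij + e_ijk

with ``a`` the condition effect (tumor vs placebo), ``b`` the tumor
model (cell line), ``(ab)`` their interaction, and sum-to-zero
constraints on the effects.  Only the balanced 2x2 layout is supported
(equal cell counts), which admits the classical closed-form
decomposition from cell means; a significant interaction marks a peak
whose tumor response differs between the two cancer models, i.e.
tumor-type specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .features import SubtractedMatrix

#: Default interaction-screen thresholds: a loose exploratory one and a
#: strict one guarding against false positives over ~47 parallel tests.
LOOSE_ALPHA = 0.05
STRICT_ALPHA = 0.002


@dataclass(frozen=True)
class AnovaResult:
    """Sums of squares, F statistics and p-values for one peak."""

    ss_condition: float
    ss_model: float
    ss_interaction: float
    ss_error: float
    df_condition: int
    df_model: int
    df_interaction: int
    df_error: int
    f_condition: float
    f_model: float
    f_interaction: float
    p_condition: float
    p_model: float
    p_interaction: float

    @property
    def ss_total(self) -> float:
        return self.ss_condition + self.ss_model + self.ss_interaction + self.ss_error

    def interaction_significant(self, alpha: float = STRICT_ALPHA) -> bool:
        """Model-specific flag at the given interaction threshold."""
        return bool(self.p_interaction < alpha)


def two_way_anova(y, condition, model) -> AnovaResult:
    """Classical balanced 2x2 decomposition from cell means.

    Parameters
    ----------
    y
        Observations (normalized subtracted values of one peak).
    condition, model
        Factor labels per observation; each must have exactly two
        levels with equal counts in all four cells.
    """
    y = np.asarray(y, dtype=float)
    condition = np.asarray(condition)
    model = np.asarray(model)
    if not (y.shape == condition.shape == model.shape) or y.ndim != 1:
        raise DataError("y, condition and model must be 1-D and equally long")
    a_levels = np.unique(condition)
    b_levels = np.unique(model)
    if a_levels.size != 2 or b_levels.size != 2:
        raise DataError(
            f"need exactly 2 levels per factor, got {a_levels.size} conditions "
            f"and {b_levels.size} models"
        )
    cells = {}
    counts = set()
    for ai in a_levels:
        for bj in b_levels:
            cell = y[(condition == ai) & (model == bj)]
            cells[(ai, bj)] = cell
            counts.add(cell.size)
    if len(counts) != 1:
        raise DataError(
            "unbalanced design: cell counts differ "
            f"({sorted(len(v) for v in cells.values())}); only the balanced "
            "2x2 layout is supported"
        )
    n = counts.pop()
    if n < 2:
        raise DataError("each cell needs at least 2 observations")

    grand = y.mean()
    cm = np.array([[cells[(ai, bj)].mean() for bj in b_levels] for ai in a_levels])
    row = cm.mean(axis=1)  # condition means
    col = cm.mean(axis=0)  # model means
    ss_a = 2 * n * float(np.sum((row - grand) ** 2))
    ss_b = 2 * n * float(np.sum((col - grand) ** 2))
    inter = cm - row[:, None] - col[None, :] + grand
    ss_ab = n * float(np.sum(inter**2))
    ss_err = float(
        sum(np.sum((cells[(ai, bj)] - cm[i, j]) ** 2)
            for i, ai in enumerate(a_levels) for j, bj in enumerate(b_levels))
    )
    df_err = 4 * n - 4
    ms_err = ss_err / df_err
    if ms_err == 0.0:  # exact cell means: F degenerates to 0 or +inf
        f_a, f_b, f_ab = (np.inf if s > 0 else 0.0 for s in (ss_a, ss_b, ss_ab))
    else:
        f_a, f_b, f_ab = (s / ms_err for s in (ss_a, ss_b, ss_ab))
    p_a, p_b, p_ab = (float(stats.f.sf(f, 1, df_err)) for f in (f_a, f_b, f_ab))
    return AnovaResult(
        ss_condition=ss_a,
        ss_model=ss_b,
        ss_interaction=ss_ab,
        ss_error=ss_err,
        df_condition=1,
        df_model=1,
        df_interaction=1,
        df_error=df_err,
        f_condition=float(f_a),
        f_model=float(f_b),
        f_interaction=float(f_ab),
        p_condition=p_a,
        p_model=p_b,
        p_interaction=p_ab,
    )


def anova_table(
    R: SubtractedMatrix,
    loose: float = LOOSE_ALPHA,
    strict: float = STRICT_ALPHA,
) -> pd.DataFrame:
    """Run the 2x2 ANOVA for every peak of a pooled four-group analysis set.

    Returns one row per peak with SS/F/p per effect and interaction
    flags at the loose and strict thresholds.
    """
    cond = R.labels["condition"].to_numpy()
    model = R.labels["model"].to_numpy()
    rows = []
    for peak in R.peak_ids:
        res = two_way_anova(R.values[peak].to_numpy(dtype=float), cond, model)
        rows.append(
            {
                "peak": peak,
                "ss_condition": res.ss_condition,
                "ss_model": res.ss_model,
                "ss_interaction": res.ss_interaction,
                "ss_error": res.ss_error,
                "f_condition": res.f_condition,
                "f_model": res.f_model,
                "f_interaction": res.f_interaction,
                "p_condition": res.p_condition,
                "p_model": res.p_model,
                "p_interaction": res.p_interaction,
                "interaction_loose": res.p_interaction < loose,
                "interaction_strict": res.p_interaction < strict,
            }
        )
    return pd.DataFrame(rows)


def interaction_screen(
    table: pd.DataFrame,
    loose: float = LOOSE_ALPHA,
    strict: float = STRICT_ALPHA,
) -> tuple[list[str], list[str]]:
    """Peaks with interaction p below the loose threshold, and the strict
    subset, each sorted by ascending interaction p."""
    ordered = table.sort_values(["p_interaction", "peak"], kind="stable")
    loose_peaks = ordered.loc[ordered["p_interaction"] < loose, "peak"].tolist()
    strict_peaks = ordered.loc[ordered["p_interaction"] < strict, "peak"].tolist()
    return loose_peaks, strict_peaks
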