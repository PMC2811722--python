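"""Seeded synthetic studies with the structure the analysis assumes.

The generator emulates a two-tumor-model urinary-volatile study: two
cell-line models x {tumor, placebo}, 25 animals per group, urine
profiled at an early (pre-tumor) and a late (terminal) timepoint, with
47 shared GC/MS peaks.  Peak heights are log-normal: effects and noise
act additively on the log-intensity scale and tables are returned on the
linear scale.

The log-intensity of sample ``s`` in group ``(m, c)`` at timepoint ``t``
for peak ``p`` is::

    mu_p + tau_p*[t=late] + (delta_p + gamma_{p,m})*[t=late and c=tumor] + eps

with ``eps ~ Normal(0, sigma_p^2)`` i.i.d.  ``tau_p`` is the "term
effect" shared by tumor and placebo animals (husbandry, ageing, season);
``delta_p`` the shared tumor effect (negative for the predominant
down-regulation); ``gamma_{p,m}`` a model-specific interaction summing
to zero over models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatogram import TIC
from .errors import ConfigError, DataError
from .tables import CONDITIONS, TIMEPOINTS, PeakTable, peak_ids

#: Cubic tumor growth fits (volume in mm^3 versus days post injection)
#: for the two flank tumor models.
GROWTH_COEFFS: dict[str, tuple[float, float, float, float]] = {
    "LKR": (0.092, -2.8, 38.0, -18.0),
    "LLC": (0.16, -0.83, 3.5, -4.0),
}


def tumor_volume(largest_diameter: float, perpendicular_diameter: float) -> float:
    """Caliper estimate of flank tumor volume, ``3.14 * d * p^2 / 6``.

    The coefficient is the conventional rounded 3.14 of the modified
    ellipsoid formula, kept as such rather than ``pi``.
    """
    if largest_diameter < 0 or perpendicular_diameter < 0:
        raise ConfigError("tumor diameters must be non-negative")
    return 3.14 * largest_diameter * perpendicular_diameter**2 / 6.0


def growth_curve(model: str, day):
    """Evaluate the fitted cubic growth curve of a tumor model.

    Used only to schedule how strongly "late" differs from "early" in
    synthetic studies; no per-day longitudinal samples are simulated.
    """
    try:
        coeffs = GROWTH_COEFFS[model]
    except KeyError:
        raise ConfigError(
            f"unknown tumor model {model!r}; known: {sorted(GROWTH_COEFFS)}"
        ) from None
    return np.polyval(coeffs, day)


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of a synthetic study."""

    models: tuple[str, ...] = ("LKR", "LLC")
    conditions: tuple[str, ...] = CONDITIONS
    n_per_group: int = 25
    n_peaks: int = 47
    timepoints: tuple[str, ...] = TIMEPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be at least 2")
        if self.n_peaks < 1:
            raise ConfigError("n_peaks must be at least 1")
        if len(self.models) < 1:
            raise ConfigError("at least one tumor model required")
        if tuple(self.conditions) != CONDITIONS:
            raise ConfigError(f"conditions must be {CONDITIONS}")
        if tuple(self.timepoints) != TIMEPOINTS:
            raise ConfigError(f"timepoints must be {TIMEPOINTS}")

    @property
    def peak_ids(self) -> list[str]:
        return peak_ids(self.n_peaks)


@dataclass(frozen=True)
class EffectSpec:
    """Per-peak effect sizes on the log-intensity scale.

    ``interaction`` has shape ``(n_models, n_peaks)`` with columns
    summing to zero, so ``tumor`` stays the shared tumor effect — the
    same sum-to-zero parameterization the downstream two-way ANOVA uses.
    """

    baseline: np.ndarray
    term: np.ndarray
    tumor: np.ndarray
    interaction: np.ndarray
    noise_sd: np.ndarray

    def __post_init__(self) -> None:
        for name in ("baseline", "term", "tumor", "noise_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 1:
                raise ConfigError(f"{name} must be a 1-D per-peak array")
        inter = np.atleast_2d(np.asarray(self.interaction, dtype=float))
        object.__setattr__(self, "interaction", inter)
        n = self.baseline.size
        for name in ("term", "tumor", "noise_sd"):
            if getattr(self, name).size != n:
                raise ConfigError(f"{name} length differs from baseline ({n})")
        if inter.shape[1] != n:
            raise ConfigError("interaction must have one column per peak")
        if np.any(self.noise_sd <= 0):
            raise ConfigError("noise_sd must be strictly positive for every peak")
        if not np.allclose(inter.sum(axis=0), 0.0, atol=1e-10):
            raise ConfigError("interaction effects must sum to zero over models")

    @property
    def n_peaks(self) -> int:
        return int(self.baseline.size)

    @property
    def differential_index(self) -> np.ndarray:
        """Indices of peaks with a nonzero shared tumor effect."""
        return np.flatnonzero(self.tumor != 0)

    @property
    def interaction_index(self) -> np.ndarray:
        """Indices of peaks with a nonzero model-specific interaction."""
        return np.flatnonzero(np.any(self.interaction != 0, axis=0))


def _spread_indices(n_total: int, n_pick: int, exclude: np.ndarray) -> np.ndarray:
    """Evenly spread ``n_pick`` indices over ``range(n_total)``, avoiding
    ``exclude``; deterministic."""
    available = np.setdiff1d(np.arange(n_total), exclude)
    if available.size < n_pick:
        raise ConfigError(
            f"cannot place {n_pick} peaks among {n_total} with "
            f"{exclude.size} excluded"
        )
    pos = np.linspace(0, available.size - 1, n_pick).round().astype(int)
    return available[np.unique(pos)]


def default_effects(
    design: StudyDesign,
    n_differential: int = 11,
    n_up: int = 2,
    n_interaction: int = 4,
    effect_size: float = 3.0,
    interaction_size: float = 2.0,
    noise_sd: float = 0.25,
    term_effect: float = 0.5,
) -> EffectSpec:
    """Study-condition defaults for the synthetic generator.

    11 of the 47 peaks carry a shared tumor effect of magnitude
    ``effect_size`` noise-SDs (|delta|/sigma = 3), predominantly
    down-regulated with ``n_up`` up-regulated exceptions; 4 disjoint
    peaks carry a model-specific interaction of ``interaction_size``
    noise-SDs with no shared effect; every peak shares a positive term
    effect.  Noise SD of 0.25 log units corresponds to a ~25% coefficient
    of variation in peak height, typical of replicate headspace GC/MS
    quantification.
    """
    n = design.n_peaks
    if n_differential + n_interaction > n:
        raise ConfigError("more planted peaks than peaks in the design")
    if n_up > n_differential:
        raise ConfigError("n_up cannot exceed n_differential")
    diff_idx = _spread_indices(n, n_differential, np.array([], dtype=int))
    inter_idx = _spread_indices(n, n_interaction, diff_idx)

    sigma = np.full(n, noise_sd)
    baseline = 4.0 + 0.05 * np.arange(n)  # ~55-550 raw intensity units
    term = np.full(n, term_effect)
    tumor = np.zeros(n)
    # predominantly down-regulated, with a minority up-regulated
    signs = -np.ones(diff_idx.size)
    signs[:n_up] = 1.0
    tumor[diff_idx] = signs * effect_size * sigma[diff_idx]

    inter = np.zeros((len(design.models), n))
    if len(design.models) >= 2 and n_interaction:
        g = interaction_size * sigma[inter_idx]
        g *= (-1.0) ** np.arange(inter_idx.size)  # alternate which model goes up
        inter[0, inter_idx] = g
        # sum-to-zero over models: spread the opposite effect over the rest
        inter[1:, inter_idx] = -g / (len(design.models) - 1)
    return EffectSpec(
        baseline=baseline,
        term=term,
        tumor=tumor,
        interaction=inter,
        noise_sd=sigma,
    )


@dataclass(frozen=True)
class GeneratedStudy:
    """A simulated study plus its ground truth."""

    design: StudyDesign
    effects: EffectSpec
    tables: dict[tuple[str, str, str], PeakTable] = field(repr=False)
    differential_peaks: tuple[str, ...]
    interaction_peaks: tuple[str, ...]
    seed: int

    def table(self, model: str, condition: str, timepoint: str) -> PeakTable:
        return self.tables[(model, condition, timepoint)]

    def labels(self) -> pd.DataFrame:
        """Long-format sample metadata (one row per animal)."""
        rows = []
        for (model, condition, timepoint), tab in self.tables.items():
            if timepoint != TIMEPOINTS[0]:
                continue
            for sid in tab.sample_ids:
                rows.append({"sample_id": sid, "model": model, "condition": condition})
        return pd.DataFrame(rows).set_index("sample_id")


def generate_peak_tables(design: StudyDesign, effects: EffectSpec) -> GeneratedStudy:
    """Generate the full set of per-(group, timepoint) peak tables.

    Deterministic: identical ``(design, effects)`` including the design
    seed yield bit-identical output.
    """
    if effects.n_peaks != design.n_peaks:
        raise ConfigError(
            f"effects describe {effects.n_peaks} peaks but the design has "
            f"{design.n_peaks}"
        )
    if effects.interaction.shape[0] != len(design.models):
        raise ConfigError(
            "interaction matrix must have one row per tumor model "
            f"({len(design.models)}), got {effects.interaction.shape[0]}"
        )
    rng = np.random.default_rng(design.seed)
    pids = design.peak_ids
    tables: dict[tuple[str, str, str], PeakTable] = {}
    for mi, model in enumerate(design.models):
        for condition in design.conditions:
            sids = [
                f"{model}_{condition}_{k + 1:02d}" for k in range(design.n_per_group)
            ]
            for timepoint in design.timepoints:
                mean = effects.baseline.copy()
                if timepoint == "late":
                    mean = mean + effects.term
                    if condition == "tumor":
                        mean = mean + effects.tumor + effects.interaction[mi]
                eps = rng.normal(
                    0.0, effects.noise_sd, size=(design.n_per_group, design.n_peaks)
                )
                values = pd.DataFrame(
                    np.exp(mean[None, :] + eps), index=sids, columns=pids
                )
                tables[(model, condition, timepoint)] = PeakTable(
                    values, model=model, condition=condition, timepoint=timepoint
                )
    return GeneratedStudy(
        design=design,
        effects=effects,
        tables=tables,
        differential_peaks=tuple(pids[i] for i in effects.differential_index),
        interaction_peaks=tuple(pids[i] for i in effects.interaction_index),
        seed=design.seed,
    )


def generate_tic(
    peak_heights,
    retention_times,
    widths,
    grid,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TIC:
    """Synthesize a TIC as a sum of Gaussians over a retention-time grid.

    intensity(t) = baseline + sum_p h_p * exp(-(t - rt_p)^2 / (2 w_p^2))
                   + Normal(0, noise_sd^2)
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DataError("retention-time grid is empty")
    heights = np.asarray(peak_heights, dtype=float)
    rts = np.asarray(retention_times, dtype=float)
    ws = np.asarray(widths, dtype=float)
    if not heights.shape == rts.shape == ws.shape:
        raise DataError("peak heights, retention times and widths differ in length")
    if np.any(ws <= 0):
        raise ConfigError("peak widths must be strictly positive")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    trace = np.full(grid.shape, float(baseline))
    for h, c, w in zip(heights, rts, ws):
        trace += h * np.exp(-((grid - c) ** 2) / (2.0 * w**2))
    if noise_sd > 0:
        trace += np.random.default_rng(seed).normal(0.0, noise_sd, size=grid.shape)
    return TIC(rt=grid, intensity=trace)


def generate_study_tics(
    study: GeneratedStudy,
    rt_start: float = 2.0,
    rt_spacing: float = 1.0,
    width: float = 0.08,
    points_per_minute: int = 50,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
) -> dict[tuple[str, str, str], dict[str, TIC]]:
    """Render every sample of a generated study as a raw TIC.

    Peak ``p`` elutes at ``rt_start + p * rt_spacing`` with a common
    Gaussian width; the sample's tabulated heights become the Gaussian
    amplitudes, so chromatogram quantification can be round-tripped
    against the generating tables.
    """
    n = study.design.n_peaks
    rts = rt_start + rt_spacing * np.arange(n)
    span = rts[-1] + 10 * width + rt_start
    grid = np.arange(0.0, span, 1.0 / points_per_minute)
    # snap peak centres onto the grid so the window maximum is exact
    rts = grid[np.searchsorted(grid, rts)]
    out: dict[tuple[str, str, str], dict[str, TIC]] = {}
    sub = np.random.default_rng(study.seed).integers(0, 2**31 - 1)
    for key, tab in study.tables.items():
        per_sample: dict[str, TIC] = {}
        for k, sid in enumerate(tab.sample_ids):
            per_sample[sid] = generate_tic(
                tab.values.loc[sid].to_numpy(),
                rts,
                np.full(n, width),
                grid,
                baseline=baseline,
                noise_sd=noise_sd,
                seed=int(sub) + k,
            )
        out[key] = per_sample
    return out
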