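"""End-to-end pipeline: simulate -> subtract -> screen -> ANOVA ->
PCA/SVM -> exhaustive panel search, with every artifact written as CSV
and the configuration echoed alongside.

Identical configurations produce byte-identical report bodies; all
randomness flows from the single configured seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anova, classify, features, panels, simulate
from .chromatogram import log_transform
from .errors import VocPanelError
from .io import RunConfig, write_peak_table

logger = logging.getLogger(__name__)

#: Class coding used everywhere downstream: tumor animals are positive.
CLASS_CODE = {"tumor": 1, "placebo": -1}


def class_labels(R: features.SubtractedMatrix) -> pd.Series:
    """+1 (tumor) / -1 (placebo) labels aligned with the matrix rows."""
    return R.labels["condition"].map(CLASS_CODE)


def model_analysis_set(
    study: simulate.GeneratedStudy, model: str
) -> features.SubtractedMatrix:
    """Pooled, normalized subtracted matrix for one tumor model.

    Peak heights are log-transformed before the term-effect subtraction,
    so the difference acts on the scale where effects and noise are
    additive; the per-peak z-scoring follows.
    """
    mats = [
        features.subtract_term_effect(
            log_transform(study.table(model, cond, "early")),
            log_transform(study.table(model, cond, "late")),
        )
        for cond in study.design.conditions
    ]
    return features.normalize_subtracted(features.combine(mats))


def pooled_analysis_set(study: simulate.GeneratedStudy) -> features.SubtractedMatrix:
    """Four-group pooled matrix (both models), normalized, for the ANOVA."""
    mats = [
        features.subtract_term_effect(
            log_transform(study.table(m, c, "early")),
            log_transform(study.table(m, c, "late")),
        )
        for m in study.design.models
        for c in study.design.conditions
    ]
    return features.normalize_subtracted(features.combine(mats))


@dataclass
class PipelineResult:
    """In-memory bundle of everything a run produced."""

    config: RunConfig
    study: simulate.GeneratedStudy = field(repr=False)
    screening: dict[str, pd.DataFrame] = field(repr=False)
    selected: dict[str, list[str]]
    anova_report: pd.DataFrame = field(repr=False)
    interaction_loose: list[str]
    interaction_strict: list[str]
    pca_svm: pd.DataFrame = field(repr=False)
    searches: dict[str, panels.SearchResult] = field(repr=False)
    best_panels: pd.DataFrame = field(repr=False)


def _pca_svm_metrics(
    R: features.SubtractedMatrix, config: RunConfig
) -> dict[str, float | None]:
    """Train-set PCA scores + SVM classification for one model (the
    scores-plot analysis: all samples projected and classified at once)."""
    X = R.values.to_numpy(dtype=float)
    y = class_labels(R).to_numpy()
    pca = classify.pca_fit(X, config.pca_components)
    scores = classify.pca_project(pca, X)
    model = classify.svm_train(scores, y, sigma=config.sigma, C=config.C)
    pred, _ = classify.svm_predict(model, scores)
    m = classify.confusion_metrics(pred, y)
    fpr, tpr = classify.roc_point(m)
    return {
        "accuracy": 100 * m.accuracy,
        "sensitivity": None if m.sensitivity is None else 100 * m.sensitivity,
        "specificity": None if m.specificity is None else 100 * m.specificity,
        "misclassified": m.misclassified,
        "n": m.total,
        "fpr": fpr,
        "tpr": tpr,
        "pc1_var": pca.explained_variance_ratio[0],
        "pc2_var": (
            pca.explained_variance_ratio[1] if pca.n_components > 1 else np.nan
        ),
    }


def _candidates(selected: list[str], report: pd.DataFrame, cap: int) -> list[str]:
    """Screened peaks, truncated to the cap by ascending p-value."""
    if len(selected) <= cap:
        return selected
    return report.sort_values(["p_value", "peak"], kind="stable")["peak"].tolist()[
        :cap
    ]


def run_pipeline(config: RunConfig, outdir) -> PipelineResult:
    """Execute the full analysis on a freshly generated synthetic study.

    Writes per-group peak tables, the ground truth, screening and ANOVA
    reports, the PCA/SVM summary, one ranked panel table per (model,
    protocol), and a best-panel summary, plus the echoed configuration.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    current = {"stage": "init"}

    def _stage(name: str):
        current["stage"] = name
        logger.info("stage=%s seed=%d elapsed=%.1fs",
                    name, config.seed, time.perf_counter() - t0)

    try:
        _stage("simulate")
        design = simulate.StudyDesign(
            n_per_group=config.n_per_group,
            n_peaks=config.n_peaks,
            seed=config.seed,
        )
        effects = simulate.default_effects(design, **config.effects)
        study = simulate.generate_peak_tables(design, effects)
        for (m, c, t), tab in study.tables.items():
            write_peak_table(tab, out / f"peaks_{m}_{c}_{t}.csv")
        truth = pd.DataFrame(
            {
                "peak": study.design.peak_ids,
                "differential": [
                    p in study.differential_peaks for p in study.design.peak_ids
                ],
                "interaction": [
                    p in study.interaction_peaks for p in study.design.peak_ids
                ],
            }
        )
        truth.to_csv(out / "ground_truth.csv", index=False)

        _stage("subtract")
        per_model = {m: model_analysis_set(study, m) for m in design.models}
        for m, R in per_model.items():
            R.values.to_csv(out / f"subtracted_normalized_{m}.csv")

        _stage("screen")
        screening, selected = {}, {}
        for m, R in per_model.items():
            sel, rep = features.screen_peaks(
                R, alpha=config.screen_alpha, test=config.screen_test
            )
            screening[m], selected[m] = rep, sel
            rep.to_csv(out / f"screening_{m}.csv", index=False)

        _stage("anova")
        pooled = pooled_analysis_set(study)
        anova_rep = anova.anova_table(
            pooled, loose=config.anova_loose, strict=config.anova_strict
        )
        anova_rep.to_csv(out / "anova.csv", index=False)
        loose, strict = anova.interaction_screen(
            anova_rep, loose=config.anova_loose, strict=config.anova_strict
        )

        _stage("classify")
        pca_rows = []
        for m, R in per_model.items():
            row = {"model": m}
            row.update(_pca_svm_metrics(R, config))
            pca_rows.append(row)
        pca_svm = pd.DataFrame(pca_rows)
        pca_svm.to_csv(out / "pca_svm.csv", index=False)

        _stage("search")
        cfg = panels.ClassifierConfig(
            sigma=config.sigma, C=config.C, paper_mode=config.paper_mode
        )
        searches: dict[str, panels.SearchResult] = {}
        best_rows = []
        for m, R in per_model.items():
            cands = _candidates(selected[m], screening[m], config.max_candidates)
            if not cands:
                logger.warning("model %s: no screened peaks; search skipped", m)
                continue
            X, yv = R.values, class_labels(R).to_numpy()
            for protocol in config.protocols:
                if protocol == "transfer":
                    continue  # handled below, needs the other model
                key = f"{m}_{protocol}"
                res = panels.exhaustive_search(
                    X, yv, cands, protocol=protocol, config=cfg,
                    seed=config.seed, cv_k=config.cv_k,
                    n_train_per_class=config.holdout_train,
                    n_test_per_class=config.holdout_test,
                )
                searches[key] = res
                res.table.to_csv(out / f"search_{key}.csv", index=False)
                best_rows.append({"search": key, **_best_row(res)})
        if "transfer" in config.protocols and len(design.models) == 2:
            for m_train, m_test in (design.models, design.models[::-1]):
                R_tr, R_te = per_model[m_train], per_model[m_test]
                cands = _candidates(
                    selected[m_train], screening[m_train], config.max_candidates
                )
                if not cands:
                    continue
                key = f"{m_train}_to_{m_test}_transfer"
                res = panels.exhaustive_search(
                    R_tr.values, class_labels(R_tr).to_numpy(), cands,
                    protocol="transfer", config=cfg,
                    test_X=R_te.values, test_y=class_labels(R_te).to_numpy(),
                )
                searches[key] = res
                res.table.to_csv(out / f"search_{key}.csv", index=False)
                best_rows.append({"search": key, **_best_row(res)})
        best = pd.DataFrame(best_rows)
        best.to_csv(out / "best_panels.csv", index=False)

        config.to_yaml(out / "config.yaml")
        _stage("done")
        return PipelineResult(
            config=config,
            study=study,
            screening=screening,
            selected=selected,
            anova_report=anova_rep,
            interaction_loose=loose,
            interaction_strict=strict,
            pca_svm=pca_svm,
            searches=searches,
            best_panels=best,
        )
    except VocPanelError as exc:
        raise type(exc)(f"stage {current['stage']}: {exc}") from exc
    except Exception as exc:  # annotate unexpected failures with the stage
        raise VocPanelError(f"stage {current['stage']}: {exc}") from exc


def _best_row(res: panels.SearchResult) -> dict:
    r = res.results[0]
    return {
        "peaks": ";".join(r.peaks),
        "accuracy_mean": r.accuracy_mean,
        "accuracy_sem": r.accuracy_sem,
        "sensitivity_mean": r.sensitivity_mean,
        "specificity_mean": r.specificity_mean,
    }
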