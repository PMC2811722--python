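"""Exhaustive peak-panel evaluation under cross-validation, hold-out and
cross-model transfer protocols.

Every non-empty subset of a candidate peak list (2^p - 1 panels; 2047
for the canonical 11 screened peaks) is scored with a soft-margin RBF
classifier under one of three protocols:

``cv10``
    Stratified 10-fold cross-validation: each class's 25 samples are
    randomly partitioned into 10 folds of 1-3 animals; fold ``j`` of the
    tumor class is tested together with fold ``j`` of the placebo class
    while the classifier trains on the remaining folds.
``holdout``
    13 training / 12 test animals per class, a single random split per
    seed (repeatable for a mean +/- SEM across seeds).
``transfer``
    Train on every sample of one tumor model, test on every sample of
    the other.

By default feature standardization (and PCA, when enabled) is fit on
training samples only; the ``paper_mode`` flag instead pools all
samples, mirroring analyses that project the complete dataset at once.
Panels are ranked by mean accuracy, then smaller size, then higher
sensitivity, then lexicographic peak order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    ConfusionMetrics,
    confusion_metrics,
    pca_fit,
    pca_project,
    svm_predict,
    svm_train,
)
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Hard ceiling on exhaustive enumeration without the override flag.
MAX_CANDIDATES = 20


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier and preprocessing settings shared by all protocols."""

    sigma: float = 0.9
    C: float = 1.0
    standardize: bool = True
    paper_mode: bool = False
    pca_components: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.C <= 0:
            raise ConfigError("sigma and C must be strictly positive")


@dataclass(frozen=True)
class FoldPlan:
    """Per-class partition of sample identifiers into k folds."""

    folds: dict[Any, list[list[str]]]
    k: int
    seed: int

    def __post_init__(self) -> None:
        for label, groups in self.folds.items():
            if len(groups) != self.k:
                raise ConfigError(f"class {label!r} has {len(groups)} != k folds")
            ids = [s for g in groups for s in g]
            if len(ids) != len(set(ids)):
                raise ConfigError(f"class {label!r} folds are not disjoint")


def make_folds(
    samples_per_class: Mapping[Any, Sequence[str]], k: int = 10, seed: int = 0
) -> FoldPlan:
    """Randomly partition each class into k folds of near-equal size.

    For 25 samples and k = 10 this yields five folds of 3 and five of 2,
    matching the 1-3 animals-per-fold protocol.  Deterministic under the
    seed.
    """
    if k < 2:
        raise ConfigError("k must be at least 2")
    rng = np.random.default_rng(seed)
    plan: dict[Any, list[list[str]]] = {}
    for label in samples_per_class:
        ids = list(samples_per_class[label])
        if len(ids) < k:
            raise ConfigError(
                f"class {label!r} has {len(ids)} samples, fewer than k={k}"
            )
        perm = [ids[i] for i in rng.permutation(len(ids))]
        base, extra = divmod(len(ids), k)
        groups, at = [], 0
        for j in range(k):
            size = base + (1 if j < extra else 0)
            groups.append(perm[at : at + size])
            at += size
        plan[label] = groups
    return FoldPlan(folds=plan, k=k, seed=seed)


def enumerate_subsets(peaks: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2^p - 1 non-empty subsets in lexicographic (prefix) order."""
    peaks = list(peaks)
    if not peaks:
        raise DataError("no candidate peaks to enumerate")
    p = len(peaks)
    index_subsets = sorted(
        chain.from_iterable(combinations(range(p), r) for r in range(1, p + 1))
    )
    return [tuple(peaks[i] for i in t) for t in index_subsets]


@dataclass(frozen=True)
class PanelResult:
    """Aggregated classification scores of one peak panel (percent)."""

    peaks: tuple[str, ...]
    protocol: str
    n_evals: int
    accuracy_mean: float
    accuracy_sem: float
    sensitivity_mean: float | None
    sensitivity_sem: float | None
    specificity_mean: float | None
    specificity_sem: float | None

    @property
    def roc(self) -> tuple[float | None, float | None]:
        """Mean ROC-space point ``(1 - sp, se)`` on the 0-1 scale."""
        fpr = None if self.specificity_mean is None else 1 - self.specificity_mean / 100
        tpr = None if self.sensitivity_mean is None else self.sensitivity_mean / 100
        return fpr, tpr


# ---------------------------------------------------------------------------
# internal split machinery


@dataclass(frozen=True)
class _Split:
    train_idx: np.ndarray
    test_idx: np.ndarray
    mu: np.ndarray | None  # standardization stats over all columns
    sd: np.ndarray | None


def _split_stats(
    arr: np.ndarray, train_idx: np.ndarray, test_idx: np.ndarray,
    config: ClassifierConfig,
) -> _Split:
    if not config.standardize:
        return _Split(train_idx, test_idx, None, None)
    rows = np.concatenate([train_idx, test_idx]) if config.paper_mode else train_idx
    ref = arr[rows]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return _Split(train_idx, test_idx, mu, sd)


def _eval_split(
    arr: np.ndarray, y: np.ndarray, cols: np.ndarray, split: _Split,
    config: ClassifierConfig,
) -> ConfusionMetrics:
    Xtr = arr[np.ix_(split.train_idx, cols)]
    Xte = arr[np.ix_(split.test_idx, cols)]
    if split.mu is not None:
        Xtr = (Xtr - split.mu[cols]) / split.sd[cols]
        Xte = (Xte - split.mu[cols]) / split.sd[cols]
    if config.pca_components is not None:
        ref = np.vstack([Xtr, Xte]) if config.paper_mode else Xtr
        pm = pca_fit(ref, config.pca_components)
        Xtr = pca_project(pm, Xtr)
        Xte = pca_project(pm, Xte)
    model = svm_train(Xtr, y[split.train_idx], sigma=config.sigma, C=config.C)
    labels, _ = svm_predict(model, Xte)
    return confusion_metrics(labels, y[split.test_idx])


def _aggregate(
    peaks: tuple[str, ...], protocol: str, metrics: Sequence[ConfusionMetrics]
) -> PanelResult:
    def mean_sem(vals: list[float]) -> tuple[float | None, float | None]:
        if not vals:
            return None, None
        arr = 100.0 * np.asarray(vals)
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        return float(arr.mean()), sem

    acc = [m.accuracy for m in metrics]
    se = [m.sensitivity for m in metrics if m.sensitivity is not None]
    sp = [m.specificity for m in metrics if m.specificity is not None]
    if len(se) < len(metrics) or len(sp) < len(metrics):
        logger.debug(
            "panel %s: %d/%d splits lacked a class; undefined rates excluded",
            peaks, 2 * len(metrics) - len(se) - len(sp), len(metrics),
        )
    acc_m, acc_s = mean_sem(acc)
    se_m, se_s = mean_sem(se)
    sp_m, sp_s = mean_sem(sp)
    return PanelResult(
        peaks=peaks,
        protocol=protocol,
        n_evals=len(metrics),
        accuracy_mean=acc_m,
        accuracy_sem=acc_s,
        sensitivity_mean=se_m,
        sensitivity_sem=se_s,
        specificity_mean=sp_m,
        specificity_sem=sp_s,
    )


def _as_matrix(X: pd.DataFrame, y) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    if not isinstance(X, pd.DataFrame):
        raise DataError("X must be a samples x peaks DataFrame")
    arr = X.to_numpy(dtype=float)
    y = np.asarray(y)
    if y.shape[0] != arr.shape[0]:
        raise DataError("y must have one label per sample row")
    if set(np.unique(y).tolist()) != {-1, 1}:
        raise DataError("y must be coded -1/+1 with both classes present")
    return arr, y.astype(int), X.index


def _cols(X: pd.DataFrame, subset: Sequence[str]) -> np.ndarray:
    try:
        return np.asarray([X.columns.get_loc(p) for p in subset], dtype=int)
    except KeyError as exc:
        raise DataError(f"unknown peak identifier in subset: {exc}") from None


def _cv_split_indices(
    index: pd.Index, y: np.ndarray, folds: FoldPlan
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pair fold j of each class as the test set of fold j."""
    pos = {sid: i for i, sid in enumerate(index)}
    labels = list(folds.folds)
    if len(labels) != 2:
        raise ConfigError("fold plan must cover exactly two classes")
    planned = {s for groups in folds.folds.values() for g in groups for s in g}
    if planned != set(index):
        raise DataError("fold plan samples do not match the data's sample ids")
    out = []
    all_rows = np.arange(len(index))
    for j in range(folds.k):
        test = np.asarray(
            sorted(pos[s] for lab in labels for s in folds.folds[lab][j]), dtype=int
        )
        train = np.setdiff1d(all_rows, test)
        out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# public protocols


def cross_validate(
    X: pd.DataFrame,
    y,
    subset: Sequence[str],
    folds: FoldPlan,
    config: ClassifierConfig = ClassifierConfig(),
) -> PanelResult:
    """Score one panel by paired-fold cross-validation.

    A test fold missing one class is permitted; its undefined
    sensitivity or specificity is simply excluded from that metric's
    mean and SEM.
    """
    arr, y, index = _as_matrix(X, y)
    cols = _cols(X, subset)
    metrics = []
    for train_idx, test_idx in _cv_split_indices(index, y, folds):
        split = _split_stats(arr, train_idx, test_idx, config)
        metrics.append(_eval_split(arr, y, cols, split, config))
    return _aggregate(tuple(subset), "cv10", metrics)


def holdout_eval(
    X: pd.DataFrame,
    y,
    subset: Sequence[str],
    n_train_per_class: int = 13,
    n_test_per_class: int = 12,
    seed: int = 0,
    config: ClassifierConfig = ClassifierConfig(),
    n_repeats: int = 1,
) -> PanelResult:
    """Score one panel on random train/test splits (13/12 per class)."""
    arr, y, _ = _as_matrix(X, y)
    cols = _cols(X, subset)
    need = n_train_per_class + n_test_per_class
    rng = np.random.default_rng(seed)
    class_rows = {lab: np.flatnonzero(y == lab) for lab in (-1, 1)}
    for lab, rows in class_rows.items():
        if rows.size < need:
            raise DataError(
                f"class {lab} has {rows.size} samples, fewer than the requested "
                f"{n_train_per_class}+{n_test_per_class} split"
            )
    metrics = []
    for _ in range(n_repeats):
        train_parts, test_parts = [], []
        for rows in class_rows.values():
            perm = rng.permutation(rows)
            train_parts.append(perm[:n_train_per_class])
            test_parts.append(perm[n_train_per_class:need])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.sort(np.concatenate(test_parts))
        split = _split_stats(arr, train_idx, test_idx, config)
        metrics.append(_eval_split(arr, y, cols, split, config))
    return _aggregate(tuple(subset), "holdout", metrics)


def transfer_eval(
    train_X: pd.DataFrame,
    train_y,
    test_X: pd.DataFrame,
    test_y,
    subset: Sequence[str],
    config: ClassifierConfig = ClassifierConfig(),
) -> PanelResult:
    """Train on all samples of one tumor model, test on all of the other.

    Standardization (and PCA) is always fitted on the training dataset
    and applied to the test dataset, regardless of ``paper_mode``.
    """
    if list(train_X.columns) != list(test_X.columns):
        raise DataError("training and test datasets must share peak identifiers")
    arr_tr, y_tr, _ = _as_matrix(train_X, train_y)
    arr_te = test_X.to_numpy(dtype=float)
    y_te = np.asarray(test_y).astype(int)
    if y_te.shape[0] != arr_te.shape[0]:
        raise DataError("test_y must have one label per test sample")
    arr = np.vstack([arr_tr, arr_te])
    y = np.concatenate([y_tr, y_te])
    train_idx = np.arange(arr_tr.shape[0])
    test_idx = arr_tr.shape[0] + np.arange(arr_te.shape[0])
    cols = _cols(train_X, subset)
    cfg = ClassifierConfig(
        sigma=config.sigma, C=config.C, standardize=config.standardize,
        paper_mode=False, pca_components=config.pca_components,
    )
    split = _split_stats(arr, train_idx, test_idx, cfg)
    metrics = [_eval_split(arr, y, cols, split, cfg)]
    return _aggregate(tuple(subset), "transfer", metrics)


# ---------------------------------------------------------------------------
# exhaustive search


@dataclass(frozen=True)
class SearchResult:
    """Ranked outcome of an exhaustive panel search."""

    results: list[PanelResult] = field(repr=False)
    table: pd.DataFrame = field(repr=False)
    protocol: str

    @property
    def best(self) -> list[PanelResult]:
        """The top stratum: every panel tied with the best mean accuracy."""
        top = self.results[0].accuracy_mean
        return [r for r in self.results if r.accuracy_mean == top]


def _rank_key(result: PanelResult, order: dict[str, int]):
    sens = result.sensitivity_mean if result.sensitivity_mean is not None else -1.0
    return (
        -result.accuracy_mean,
        len(result.peaks),
        -sens,
        tuple(order[p] for p in result.peaks),
    )


def exhaustive_search(
    X: pd.DataFrame,
    y,
    candidate_peaks: Sequence[str],
    protocol: str = "cv10",
    config: ClassifierConfig = ClassifierConfig(),
    folds: FoldPlan | None = None,
    seed: int = 0,
    cv_k: int = 10,
    n_train_per_class: int = 13,
    n_test_per_class: int = 12,
    n_repeats: int = 1,
    test_X: pd.DataFrame | None = None,
    test_y=None,
    allow_large: bool = False,
) -> SearchResult:
    """Evaluate every non-empty subset of the candidate peaks.

    For the canonical 11 candidates this is 2047 classifier evaluations
    per split.  More than 20 candidates is refused (2^p blow-up) unless
    ``allow_large`` is set.
    """
    candidates = list(candidate_peaks)
    if len(candidates) > MAX_CANDIDATES and not allow_large:
        raise ConfigError(
            f"{len(candidates)} candidate peaks would enumerate "
            f"2^{len(candidates)}-1 panels; pass allow_large=True to override"
        )
    if protocol not in ("cv10", "holdout", "transfer"):
        raise ConfigError(f"unknown protocol {protocol!r}")

    # Build the split list once; every subset reuses it.
    if protocol == "transfer":
        if test_X is None or test_y is None:
            raise ConfigError("transfer protocol needs test_X and test_y")
        if list(X.columns) != list(test_X.columns):
            raise DataError("training and test datasets must share peak identifiers")
        arr_tr, y_tr, _ = _as_matrix(X, y)
        arr = np.vstack([arr_tr, test_X.to_numpy(dtype=float)])
        y_all = np.concatenate([y_tr, np.asarray(test_y).astype(int)])
        pairs = [(np.arange(arr_tr.shape[0]),
                  arr_tr.shape[0] + np.arange(len(test_X)))]
        cfg = ClassifierConfig(
            sigma=config.sigma, C=config.C, standardize=config.standardize,
            paper_mode=False, pca_components=config.pca_components,
        )
        ref_frame = X
    else:
        arr, y_all, index = _as_matrix(X, y)
        cfg = config
        ref_frame = X
        if protocol == "cv10":
            if folds is None:
                per_class = {
                    lab: [s for s, lab_s in zip(index, y_all) if lab_s == lab]
                    for lab in (1, -1)
                }
                folds = make_folds(per_class, k=cv_k, seed=seed)
            pairs = _cv_split_indices(index, y_all, folds)
        else:
            need = n_train_per_class + n_test_per_class
            rng = np.random.default_rng(seed)
            class_rows = {lab: np.flatnonzero(y_all == lab) for lab in (-1, 1)}
            for lab, rows in class_rows.items():
                if rows.size < need:
                    raise DataError(
                        f"class {lab} has {rows.size} samples, fewer than "
                        f"{need} required for the hold-out split"
                    )
            pairs = []
            for _ in range(n_repeats):
                tr_parts, te_parts = [], []
                for rows in class_rows.values():
                    perm = rng.permutation(rows)
                    tr_parts.append(perm[:n_train_per_class])
                    te_parts.append(perm[n_train_per_class:need])
                pairs.append(
                    (np.sort(np.concatenate(tr_parts)),
                     np.sort(np.concatenate(te_parts)))
                )

    splits = [_split_stats(arr, tr, te, cfg) for tr, te in pairs]
    col_of = {p: ref_frame.columns.get_loc(p) for p in candidates}
    results = []
    for subset in enumerate_subsets(candidates):
        cols = np.asarray([col_of[p] for p in subset], dtype=int)
        metrics = [_eval_split(arr, y_all, cols, s, cfg) for s in splits]
        results.append(_aggregate(subset, protocol, metrics))

    order = {p: i for i, p in enumerate(candidates)}
    results.sort(key=lambda r: _rank_key(r, order))
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(results) + 1),
            "peaks": [";".join(r.peaks) for r in results],
            "n_peaks": [len(r.peaks) for r in results],
            "accuracy_mean": [r.accuracy_mean for r in results],
            "accuracy_sem": [r.accuracy_sem for r in results],
            "sensitivity_mean": [r.sensitivity_mean for r in results],
            "sensitivity_sem": [r.sensitivity_sem for r in results],
            "specificity_mean": [r.specificity_mean for r in results],
            "specificity_sem": [r.specificity_sem for r in results],
            "fpr": [r.roc[0] for r in results],
            "tpr": [r.roc[1] for r in results],
        }
    )
    return SearchResult(results=results, table=table, protocol=protocol)
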