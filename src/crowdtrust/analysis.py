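"""Statistical screening and prediction of worker performance.

The pipeline mirrors the study design: (1) Pearson-correlate each metric
with per-worker mean PCC, flagging which survive Bonferroni correction
over the four primary metrics; (2) sweep the penalized-time weighting
constant c over a grid and ask whether any value yields a significantly
positive correlation; (3) regress mean PCC on every non-empty subset of
the correlative metrics with worker-level 5-fold cross-validation,
reporting MAE in percentage points; (4) evaluate generalization by
fitting on one worker cohort and measuring MAE on a disjoint one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression

from .classifier import mean_pcc_by_worker
from .config import StudyConfig
from .data_model import WorkerResponse
from .exceptions import (
    ConstantInputError,
    ContaminationError,
    InsufficientDataError,
    UndefinedMetricError,
)
from .metrics import compute_rmscl1, pt_components

ALPHA = 0.05
N_PRIMARY_METRICS = 4  # MSCL1, MPIL1, PT, mean time
BASE_FEATURES = ("mscl1", "mpil1", "mean_time_s")

# Underlying per-worker data-point count backing each mean-valued metric,
# used for the minimum-data-points analysis gate.
_COUNT_COLUMNS = {
    "mscl1": "n_retest",
    "mpil1": "n_videos",
    "pt": "n_videos",
    "mean_time_s": "n_videos",
    "mean_pcc": "n_videos",
    "rmscl1": "n_revised",
}


@dataclass(frozen=True)
class CorrelationResult:
    metric_name: str
    n_workers: int
    r: float
    p_value: float
    passes_bonferroni: bool


@dataclass(frozen=True)
class RegressionReport:
    """MAE of one metric subset's linear prediction of mean PCC.

    ``mae_pct`` is the mean absolute error of the predicted mean PCC, in
    percentage points. ``cohort_mode`` is ``cv_per_subset`` (each subset
    keeps every worker with that subset defined), ``cv_intersection``
    (restricted to workers with all base metrics defined) or
    ``cross_cohort`` (fit on one cohort, evaluated on a disjoint one; then
    ``mae_insample_pct`` carries the training-cohort error).
    """

    feature_subset: tuple[str, ...]
    mae_pct: float
    n_workers: int
    cohort_mode: str
    coefficients: dict[str, float]
    seed: int | None
    mae_insample_pct: float | None = None


@dataclass(frozen=True)
class SweepResult:
    c_values: np.ndarray
    r_per_c: np.ndarray
    p_per_c: np.ndarray
    any_positive: bool
    n_workers: int


def default_c_grid() -> np.ndarray:
    """The weighting-constant grid [0.05, 10.0] in steps of 0.05 (200 points)."""
    return np.round(np.arange(1, 201) * 0.05, 10)


def correlate_metric(
    metrics: pd.DataFrame,
    metric_name: str,
    min_points: int = 5,
    alpha: float = ALPHA,
    n_metrics: int = N_PRIMARY_METRICS,
) -> CorrelationResult:
    """Pearson correlation of one metric with per-worker mean PCC.

    A worker enters the analysis only if the metric is defined and its
    underlying per-worker data-point count is at least ``min_points``.
    ``passes_bonferroni`` is ``p < alpha / n_metrics``.
    """
    count_col = _COUNT_COLUMNS.get(metric_name, "n_videos")
    eligible = (
        metrics[metric_name].notna()
        & metrics["mean_pcc"].notna()
        & (metrics[count_col] >= min_points)
    )
    sub = metrics[eligible]
    if len(sub) < 3:
        raise InsufficientDataError(
            f"{metric_name}: only {len(sub)} eligible workers, need >= 3"
        )
    x = sub[metric_name].to_numpy(dtype=float)
    y = sub["mean_pcc"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError(f"{metric_name}: input without variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        metric_name=metric_name,
        n_workers=len(sub),
        r=float(r),
        p_value=float(p),
        passes_bonferroni=bool(p < alpha / n_metrics),
    )


def screen_metrics(
    metrics: pd.DataFrame,
    metric_names: Sequence[str] = ("mscl1", "mpil1", "pt", "mean_time_s"),
    min_points: int = 5,
) -> list[CorrelationResult]:
    """Correlation screen over the primary metrics; skips metrics that lack data."""
    out = []
    for name in metric_names:
        try:
            out.append(correlate_metric(metrics, name, min_points=min_points))
        except InsufficientDataError:
            continue
    return out


def _group_by_worker(responses: Iterable[WorkerResponse]) -> dict[str, list[WorkerResponse]]:
    groups: dict[str, list[WorkerResponse]] = {}
    for r in responses:
        groups.setdefault(r.worker_id, []).append(r)
    return groups


def sweep_pt_constant(
    responses: Iterable[WorkerResponse],
    pcc_records: pd.DataFrame,
    config: StudyConfig,
    grid: np.ndarray | None = None,
    min_points: int | None = None,
) -> SweepResult:
    """Correlate penalized time with mean PCC at every c on the grid.

    PT decomposes as ``base + c * RMSCL1`` per worker, so the sweep costs
    a single pass over the responses. ``any_positive`` is true iff some
    grid point yields r > 0 with p < 0.05.
    """
    if grid is None:
        grid = default_c_grid()
    if min_points is None:
        min_points = config.min_points_analysis
    mean_pcc = mean_pcc_by_worker(pcc_records)

    bases, slopes, pccs = [], [], []
    for wid, rs in sorted(_group_by_worker(responses).items()):
        att1 = [r for r in rs if r.attempt == 1]
        n_videos = len({r.video_id for r in att1})
        if n_videos < max(config.min_videos_metrics, min_points) or wid not in mean_pcc:
            continue
        try:
            base, slope = pt_components(rs, config)
        except UndefinedMetricError:
            continue
        bases.append(base)
        slopes.append(slope)
        pccs.append(float(mean_pcc[wid]))
    n = len(bases)
    if n < 3:
        raise InsufficientDataError(f"PT defined for only {n} eligible workers")
    base_v = np.asarray(bases)
    slope_v = np.asarray(slopes)
    y = np.asarray(pccs)

    r_per_c = np.full(len(grid), np.nan)
    p_per_c = np.full(len(grid), np.nan)
    if np.ptp(y) > 0:
        for i, c in enumerate(grid):
            pt = base_v + c * slope_v
            if np.ptp(pt) == 0:
                continue
            r, p = stats.pearsonr(pt, y)
            r_per_c[i], p_per_c[i] = r, p
    with np.errstate(invalid="ignore"):
        any_positive = bool(np.any((r_per_c > 0) & (p_per_c < ALPHA)))
    return SweepResult(
        c_values=np.asarray(grid, dtype=float),
        r_per_c=r_per_c,
        p_per_c=p_per_c,
        any_positive=any_positive,
        n_workers=n,
    )


def kfold_indices(n_samples: int, k: int, seed: int) -> list[np.ndarray]:
    """Partition ``range(n_samples)`` into k near-equal folds.

    Samples are shuffled once by ``seed``; fold sizes differ by at most 1.
    """
    if n_samples < k:
        raise InsufficientDataError(f"{n_samples} samples cannot fill {k} folds")
    perm = np.random.default_rng(seed).permutation(n_samples)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def _cv_mae_pct(X: np.ndarray, y: np.ndarray, k: int, seed: int) -> float:
    """Pooled held-out MAE (percentage points) of worker-level k-fold CV."""
    folds = kfold_indices(len(y), k, seed)
    abs_errors = np.empty(len(y))
    for fold in folds:
        train = np.setdiff1d(np.arange(len(y)), fold)
        model = LinearRegression().fit(X[train], y[train])
        abs_errors[fold] = np.abs(model.predict(X[fold]) - y[fold])
    return float(abs_errors.mean() * 100.0)


def _ols_coefficients(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    model = LinearRegression().fit(X, y)
    coef = {name: float(c) for name, c in zip(names, model.coef_)}
    coef["intercept"] = float(model.intercept_)
    return coef


def all_nonempty_subsets(features: Sequence[str] = BASE_FEATURES) -> list[tuple[str, ...]]:
    return [
        tuple(c) for r in range(1, len(features) + 1) for c in combinations(features, r)
    ]


def fit_subset_regressions(
    metrics: pd.DataFrame,
    subsets: Sequence[tuple[str, ...]] | None = None,
    k: int = 5,
    seed: int = 0,
    base_features: Sequence[str] = BASE_FEATURES,
    include_intersection: bool = True,
) -> list[RegressionReport]:
    """Cross-validated MAE of mean-PCC prediction for every metric subset.

    For each subset two cohorts are evaluated: every worker with that
    subset's metrics defined (``cv_per_subset``, so cohort size varies by
    subset), and the fixed intersection cohort of workers with all
    ``base_features`` defined (``cv_intersection``). Folds partition
    workers; one worker's videos are never split across folds because the
    predicted unit is the worker's mean PCC.
    """
    if subsets is None:
        subsets = all_nonempty_subsets(base_features)
    inter_mask = metrics["mean_pcc"].notna()
    for f in base_features:
        inter_mask &= metrics[f].notna()

    reports: list[RegressionReport] = []
    for subset in subsets:
        if not subset:
            raise ValueError("feature subsets must be non-empty")
        sub_mask = metrics["mean_pcc"].notna()
        for f in subset:
            sub_mask &= metrics[f].notna()
        cohorts = [("cv_per_subset", metrics[sub_mask])]
        if include_intersection:
            cohorts.append(("cv_intersection", metrics[inter_mask]))
        for mode, cohort in cohorts:
            n = len(cohort)
            if n < k:
                raise InsufficientDataError(
                    f"subset {subset}: {n} workers < {k} folds ({mode})"
                )
            X = cohort[list(subset)].to_numpy(dtype=float)
            y = cohort["mean_pcc"].to_numpy(dtype=float)
            reports.append(
                RegressionReport(
                    feature_subset=tuple(subset),
                    mae_pct=_cv_mae_pct(X, y, k, seed),
                    n_workers=n,
                    cohort_mode=mode,
                    coefficients=_ols_coefficients(X, y, subset),
                    seed=seed,
                )
            )
    return reports


def intercept_only_cv_mae(
    metrics: pd.DataFrame,
    cohort_features: Sequence[str] = BASE_FEATURES,
    k: int = 5,
    seed: int = 0,
) -> tuple[float, int]:
    """CV MAE (pct points) of a constant predictor — the fold-train mean.

    Evaluated on the cohort of workers with all ``cohort_features``
    defined, using the same fold construction as the subset regressions;
    the baseline any informative metric subset should beat.
    """
    mask = metrics["mean_pcc"].notna()
    for f in cohort_features:
        mask &= metrics[f].notna()
    y = metrics[mask]["mean_pcc"].to_numpy(dtype=float)
    folds = kfold_indices(len(y), k, seed)
    abs_errors = np.empty(len(y))
    for fold in folds:
        train = np.setdiff1d(np.arange(len(y)), fold)
        abs_errors[fold] = np.abs(y[fold] - y[train].mean())
    return float(abs_errors.mean() * 100.0), len(y)


def cross_cohort_mae(
    train_metrics: pd.DataFrame,
    test_metrics: pd.DataFrame,
    subsets: Sequence[tuple[str, ...]] | None = None,
    base_features: Sequence[str] = BASE_FEATURES,
    train_video_ids: Sequence[str] | None = None,
    test_video_ids: Sequence[str] | None = None,
) -> list[RegressionReport]:
    """Fit on one worker cohort, measure MAE on a disjoint cohort.

    Overlapping worker ids raise :class:`ContaminationError`; overlapping
    video ids (when id sets are supplied) only warn, since distinct
    workers may legitimately have rated shared videos in other designs.
    ``mae_insample_pct`` carries the training-cohort MAE of the same fit.
    """
    overlap = set(train_metrics["worker_id"]) & set(test_metrics["worker_id"])
    if overlap:
        raise ContaminationError(
            f"{len(overlap)} worker id(s) appear in both cohorts, e.g. {sorted(overlap)[:3]}"
        )
    if train_video_ids is not None and test_video_ids is not None:
        vid_overlap = set(train_video_ids) & set(test_video_ids)
        if vid_overlap:
            warnings.warn(
                f"{len(vid_overlap)} video id(s) shared between cohorts", stacklevel=2
            )
    if subsets is None:
        subsets = all_nonempty_subsets(base_features)

    reports: list[RegressionReport] = []
    for subset in subsets:
        tr_mask = train_metrics["mean_pcc"].notna()
        te_mask = test_metrics["mean_pcc"].notna()
        for f in subset:
            tr_mask &= train_metrics[f].notna()
            te_mask &= test_metrics[f].notna()
        tr = train_metrics[tr_mask]
        te = test_metrics[te_mask]
        if len(tr) < len(subset) + 1 or te.empty:
            raise InsufficientDataError(f"subset {subset}: cohorts too small")
        Xtr = tr[list(subset)].to_numpy(dtype=float)
        ytr = tr["mean_pcc"].to_numpy(dtype=float)
        Xte = te[list(subset)].to_numpy(dtype=float)
        yte = te["mean_pcc"].to_numpy(dtype=float)
        model = LinearRegression().fit(Xtr, ytr)
        mae = float(np.abs(model.predict(Xte) - yte).mean() * 100.0)
        insample = float(np.abs(model.predict(Xtr) - ytr).mean() * 100.0)
        coef = {name: float(c) for name, c in zip(subset, model.coef_)}
        coef["intercept"] = float(model.intercept_)
        reports.append(
            RegressionReport(
                feature_subset=tuple(subset),
                mae_pct=mae,
                n_workers=len(te),
                cohort_mode="cross_cohort",
                coefficients=coef,
                seed=None,
                mae_insample_pct=insample,
            )
        )
    return reports


def postwarning_correlations(
    responses: Iterable[WorkerResponse],
    pcc_records: pd.DataFrame,
    config: StudyConfig,
    min_points: int | None = None,
) -> tuple[CorrelationResult, CorrelationResult]:
    """Correlate the two penalized-time ingredients with mean PCC.

    Returns correlations for (1) the mean total time (t1 + t2) spent on
    warned videos, and (2) RMSCL1, the revision L1 distance — each against
    per-worker mean PCC over workers with at least ``min_points`` warned
    (respectively warned-and-revised) videos.
    """
    if min_points is None:
        min_points = config.min_points_analysis
    mean_pcc = mean_pcc_by_worker(pcc_records)

    time_rows: list[tuple[float, float]] = []
    dist_rows: list[tuple[float, float]] = []
    for wid, rs in sorted(_group_by_worker(responses).items()):
        if wid not in mean_pcc:
            continue
        att1 = [r for r in rs if r.attempt == 1]
        warned = [r for r in att1 if r.warned]
        if not warned:
            continue
        y = float(mean_pcc[wid])
        if len(warned) >= min_points:
            total = np.mean(
                [r.t1_s + (r.t2_s if r.t2_s is not None else 0.0) for r in warned]
            )
            time_rows.append((float(total), y))
        revised = [r for r in warned if r.revised_answers is not None]
        if len(revised) >= min_points:
            dist_rows.append((compute_rmscl1(revised), y))

    def _corr(rows: list[tuple[float, float]], name: str) -> CorrelationResult:
        if len(rows) < 3:
            raise InsufficientDataError(
                f"{name}: only {len(rows)} eligible workers, need >= 3"
            )
        x = np.array([a for a, _ in rows])
        y = np.array([b for _, b in rows])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ConstantInputError(f"{name}: input without variance")
        r, p = stats.pearsonr(x, y)
        return CorrelationResult(
            metric_name=name,
            n_workers=len(rows),
            r=float(r),
            p_value=float(p),
            passes_bonferroni=bool(p < ALPHA / N_PRIMARY_METRICS),
        )

    return (
        _corr(time_rows, "postwarning_total_time"),
        _corr(dist_rows, "rmscl1"),
    )
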