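"""Per-worker trust and reliability metrics.

Four behavioral metrics summarize a worker's rating history without using
any diagnostic ground truth:

* MSCL1 — mean same-child L1 distance: for videos rated at both
  administrations (the second after the retest delay), the summed L1
  distance between the two answer vectors, divided by the number of paired
  videos. A test-retest reliability statistic.
* MPIL1 — mean pairwise internal L1 distance: the mean L1 distance over
  all N(N-1)/2 unordered pairs of a worker's first-attempt answer vectors
  across distinct videos. Zero indicates copy-paste answering.
* PT — penalized time: a trustworthiness score. A worker who never
  triggered the minimum-time warning receives the baseline M (the question
  count); otherwise PT is the mean total rating time (initial plus
  revision time, over all rated videos) plus c times RMSCL1, the mean L1
  distance between original and revised answers on warned videos.
* Mean time — mean initial seconds spent per first-attempt rating.

Metrics are computed only for workers who rated at least
``config.min_videos_metrics`` distinct videos; a metric whose own
precondition fails (no retest, no warnings, fewer than two videos) is
recorded as absent, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import StudyConfig
from .data_model import WorkerResponse
from .exceptions import DimensionError, UndefinedMetricError


@dataclass(frozen=True)
class WorkerMetrics:
    """One worker's metric summary; absent metrics are ``None``."""

    worker_id: str
    n_videos: int
    n_retest: int
    n_warned: int
    n_revised: int
    mscl1: float | None
    mpil1: float | None
    pt: float | None
    rmscl1: float | None
    mean_time_s: float
    mean_pcc: float


def l1_distance(a: Sequence[int], b: Sequence[int]) -> float:
    """Sum of absolute coordinate differences between two answer vectors."""
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise DimensionError(f"vector lengths differ: {av.size} vs {bv.size}")
    return float(np.abs(av - bv).sum())


def _attempt(responses: Iterable[WorkerResponse], k: int) -> dict[str, WorkerResponse]:
    return {r.video_id: r for r in responses if r.attempt == k}


def compute_mscl1(responses: Iterable[WorkerResponse]) -> float:
    """Mean same-child L1 distance over videos rated at both attempts.

    Pairs strictly by video_id; videos rated only once do not contribute
    and do not enter the denominator.
    """
    responses = list(responses)
    first = _attempt(responses, 1)
    second = _attempt(responses, 2)
    paired = [v for v in first if v in second]
    if not paired:
        raise UndefinedMetricError("MSCL1 undefined: no video rated at both attempts")
    total = sum(l1_distance(second[v].answers, first[v].answers) for v in paired)
    return total / len(paired)


def compute_mpil1(responses: Iterable[WorkerResponse]) -> float:
    """Mean pairwise internal L1 distance over first-attempt answer vectors."""
    first = _attempt(responses, 1)
    A = np.asarray([first[v].answers for v in first], dtype=float)
    N = len(A)
    if N < 2:
        raise UndefinedMetricError("MPIL1 undefined: fewer than 2 distinct videos")
    pairwise = np.abs(A[:, None, :] - A[None, :, :]).sum(axis=2)
    iu = np.triu_indices(N, k=1)
    return float(pairwise[iu].sum() / (0.5 * N * (N - 1)))


def compute_rmscl1(responses: Iterable[WorkerResponse]) -> float:
    """Revision mean same-child L1 distance over warned-and-revised videos.

    Only first-attempt ratings that triggered the warning and carry a
    revised answer vector contribute.
    """
    revised = [
        r
        for r in responses
        if r.attempt == 1 and r.warned and r.revised_answers is not None
    ]
    if not revised:
        raise UndefinedMetricError("RMSCL1 undefined: no warned video with revisions")
    return float(
        np.mean([l1_distance(r.answers, r.revised_answers) for r in revised])
    )


def pt_components(
    responses: Iterable[WorkerResponse], config: StudyConfig
) -> tuple[float, float]:
    """Decompose penalized time as ``PT(c) = base + c * slope``.

    A never-warned worker has ``(M, 0)`` — the baseline score, constant in
    c. A warned worker has base = mean total rating time over all rated
    videos (revision time counted as 0 where absent) and slope = RMSCL1.
    The decomposition makes the c-sweep a single pass over the data.
    """
    att1 = [r for r in responses if r.attempt == 1]
    if not att1:
        raise UndefinedMetricError("PT undefined: no first-attempt ratings")
    if not any(r.warned for r in att1):
        return float(config.M), 0.0
    try:
        rmscl1 = compute_rmscl1(att1)
    except UndefinedMetricError:
        raise UndefinedMetricError(
            "PT undefined: warned worker with no revision records"
        ) from None
    total_time = sum(r.t1_s + (r.t2_s if r.t2_s is not None else 0.0) for r in att1)
    return total_time / len(att1), rmscl1


def compute_pt(
    responses: Iterable[WorkerResponse],
    config: StudyConfig,
    c: float | None = None,
) -> float:
    """Penalized time at weighting constant ``c`` (default ``config.c``)."""
    base, slope = pt_components(list(responses), config)
    if c is None:
        c = config.c
    return base + c * slope


def compute_mean_time(responses: Iterable[WorkerResponse]) -> float:
    """Mean initial seconds per first-attempt rating."""
    times = [r.t1_s for r in responses if r.attempt == 1]
    if not times:
        raise UndefinedMetricError("mean time undefined: no first-attempt ratings")
    return float(np.mean(times))


def rescale_mean_time(
    mean_time_s: float, n_questions_from: int, n_questions_to: int
) -> float:
    """Proportionally rescale a mean rating time to a different question count.

    Used to carry a pilot task's observed mean time over to a task with a
    different number of questions, assuming time scales linearly with the
    question count.
    """
    if n_questions_from < 1 or n_questions_to < 1:
        raise ValueError("question counts must be positive")
    return mean_time_s * n_questions_to / n_questions_from


def compute_all_metrics(
    responses: Iterable[WorkerResponse],
    pcc_records: pd.DataFrame,
    config: StudyConfig,
) -> tuple[list[WorkerMetrics], dict]:
    """Compute the metric table for every eligible worker.

    Workers with fewer than ``config.min_videos_metrics`` distinct
    first-attempt videos are excluded and counted in the returned report;
    individual metrics whose preconditions fail are recorded as ``None``.

    Returns ``(metrics, report)`` where report holds ``n_workers_in``,
    ``n_reported`` and a mapping ``excluded`` of worker_id -> video count.
    """
    by_worker: dict[str, list[WorkerResponse]] = {}
    for r in responses:
        by_worker.setdefault(r.worker_id, []).append(r)
    mean_pcc = (
        pcc_records[pcc_records["attempt"] == 1].groupby("worker_id")["pcc"].mean()
    )

    out: list[WorkerMetrics] = []
    excluded: dict[str, int] = {}
    for wid in sorted(by_worker):
        rs = by_worker[wid]
        att1 = [r for r in rs if r.attempt == 1]
        n_videos = len({r.video_id for r in att1})
        if n_videos < config.min_videos_metrics:
            excluded[wid] = n_videos
            continue
        first_ids = {r.video_id for r in att1}
        n_retest = len(first_ids & {r.video_id for r in rs if r.attempt == 2})
        n_warned = sum(r.warned for r in att1)
        n_revised = sum(
            r.warned and r.revised_answers is not None for r in att1
        )

        def _try(fn, *args):
            try:
                return fn(*args)
            except UndefinedMetricError:
                return None

        out.append(
            WorkerMetrics(
                worker_id=wid,
                n_videos=n_videos,
                n_retest=n_retest,
                n_warned=n_warned,
                n_revised=n_revised,
                mscl1=_try(compute_mscl1, rs),
                mpil1=_try(compute_mpil1, rs),
                pt=_try(compute_pt, rs, config),
                rmscl1=_try(compute_rmscl1, rs),
                mean_time_s=compute_mean_time(rs),
                mean_pcc=float(mean_pcc.get(wid, np.nan)),
            )
        )
    report = {
        "n_workers_in": len(by_worker),
        "n_reported": len(out),
        "excluded": excluded,
    }
    return out, report


_METRIC_COLUMNS = [
    "worker_id", "n_videos", "n_retest", "n_warned", "n_revised",
    "mscl1", "mpil1", "pt", "rmscl1", "mean_time_s", "mean_pcc",
]


def metrics_frame(metrics: Iterable[WorkerMetrics]) -> pd.DataFrame:
    """Tabulate WorkerMetrics as a DataFrame; absences become NaN."""
    rows = [asdict(m) for m in metrics]
    df = pd.DataFrame(rows, columns=_METRIC_COLUMNS)
    return df
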