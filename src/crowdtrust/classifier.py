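"""PCC scoring: autism probability and probability of the correct class.

A logistic-regression classifier over the ordinal answer vector emits a
probability of autism ``p = sigmoid(b + w . a)``; the probability of the
correct class (PCC) is ``p`` when the video's true class is autism and
``1 - p`` when it is neurotypical. A worker's mean PCC over the videos
they rated is the performance criterion every trust/reliability metric is
screened against.

The classifier's weights are configuration, not code: the machinery
accepts any :class:`ClassifierSpec`, and the simulator can generate a
ground-truth one. Ordinal codes enter the linear predictor as plain
integers (no one-hot expansion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import AUTISM, CLASS_LABELS, NEUROTYPICAL, VideoRecord, WorkerResponse
from .exceptions import DimensionError, InsufficientDataError, ValidationError


@dataclass(frozen=True)
class ClassifierSpec:
    """Logistic-regression weights over the M ordinal answer features."""

    weights: tuple[float, ...]
    intercept: float
    positive_class: str = AUTISM

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if not all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise ValidationError("classifier weights and intercept must be finite")
        if self.positive_class not in CLASS_LABELS:
            raise ValidationError(f"unknown positive_class {self.positive_class!r}")

    @property
    def negative_class(self) -> str:
        return NEUROTYPICAL if self.positive_class == AUTISM else AUTISM


def predict_probability(answers: Sequence[int], spec: ClassifierSpec) -> float:
    """Probability of the positive class for one answer vector.

    Returns ``1 / (1 + exp(-(intercept + sum_j w_j a_j)))``.
    """
    a = np.asarray(answers, dtype=float)
    w = np.asarray(spec.weights, dtype=float)
    if a.shape != w.shape:
        raise DimensionError(
            f"answer vector has length {a.size}, classifier expects {w.size}"
        )
    return float(expit(spec.intercept + float(w @ a)))


def pcc(p_autism: float, true_class: str) -> float:
    """Probability of the correct class: ``p`` for autism, ``1 - p`` otherwise."""
    if not 0.0 <= p_autism <= 1.0:
        raise ValueError(f"p_autism={p_autism} outside [0, 1]")
    if true_class not in CLASS_LABELS:
        raise ValidationError(f"unknown class label {true_class!r}")
    return p_autism if true_class == AUTISM else 1.0 - p_autism


def classify(p_autism: float, threshold: float = 0.5) -> str:
    """Hard class assignment: positive class iff ``p_autism >= threshold``.

    The boundary ``p == threshold`` goes to the positive class.
    """
    if not 0.0 <= p_autism <= 1.0:
        raise ValueError(f"p_autism={p_autism} outside [0, 1]")
    return AUTISM if p_autism >= threshold else NEUROTYPICAL


def score_responses(
    responses: Iterable[WorkerResponse],
    videos: Iterable[VideoRecord] | Mapping[str, str],
    spec: ClassifierSpec,
    threshold: float = 0.5,
    use_revised: bool = False,
) -> pd.DataFrame:
    """Score every response, returning one PCC record per rating event.

    Columns: ``worker_id, video_id, attempt, p_autism, pcc,
    predicted_class``. With ``use_revised=True`` the revised answer vector
    is scored where one exists (the original otherwise).
    """
    if isinstance(videos, Mapping):
        true_class = dict(videos)
    else:
        true_class = {v.video_id: v.true_class for v in videos}
    responses = list(responses)
    if not responses:
        return pd.DataFrame(
            columns=["worker_id", "video_id", "attempt", "p_autism", "pcc", "predicted_class"]
        )
    w = np.asarray(spec.weights, dtype=float)
    vectors = []
    for r in responses:
        if r.video_id not in true_class:
            raise ValidationError(f"response references unknown video {r.video_id!r}")
        a = r.answers
        if use_revised and r.revised_answers is not None:
            a = r.revised_answers
        if len(a) != w.size:
            raise DimensionError(
                f"worker {r.worker_id!r}: answer vector length {len(a)} != {w.size}"
            )
        vectors.append(a)
    A = np.asarray(vectors, dtype=float)
    p_pos = expit(spec.intercept + A @ w)
    # orient probabilities so "p_autism" always means probability of autism
    p_autism = p_pos if spec.positive_class == AUTISM else 1.0 - p_pos
    rows = {
        "worker_id": [r.worker_id for r in responses],
        "video_id": [r.video_id for r in responses],
        "attempt": [r.attempt for r in responses],
        "p_autism": p_autism,
        "pcc": [pcc(p, true_class[r.video_id]) for p, r in zip(p_autism, responses)],
        "predicted_class": [classify(p, threshold) for p in p_autism],
    }
    return pd.DataFrame(rows)


def mean_worker_pcc(
    pcc_records: pd.DataFrame, worker_id: str, attempts: Sequence[int] = (1,)
) -> float:
    """Arithmetic mean PCC of one worker over the given attempts.

    Defaults to first-attempt ratings only, so each worker contributes a
    single performance figure; pass ``attempts=(1, 2)`` to pool attempts.
    """
    sel = pcc_records[
        (pcc_records["worker_id"] == worker_id)
        & (pcc_records["attempt"].isin(list(attempts)))
    ]
    if sel.empty:
        raise InsufficientDataError(f"no PCC records for worker {worker_id!r}")
    return float(sel["pcc"].mean())


def mean_pcc_by_worker(
    pcc_records: pd.DataFrame, attempts: Sequence[int] = (1,)
) -> pd.Series:
    """Per-worker mean PCC (attempt-1 by default), indexed by worker_id."""
    sel = pcc_records[pcc_records["attempt"].isin(list(attempts))]
    return sel.groupby("worker_id")["pcc"].mean()
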