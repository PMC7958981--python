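"""Core record types: videos, worker responses, and their invariants.

Answer vectors are stored as tuples of integer ordinal codes, one per
question; code ``a_j`` for question ``j`` lies in ``0 .. levels[j] - 1``.
A :class:`WorkerResponse` captures one rating event — a worker watching one
video at one attempt (1 = original task, 2 = re-rating after the retest
delay) — including the initial time spent, whether the minimum-time warning
fired, and any post-warning revision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .config import StudyConfig
from .exceptions import DuplicateRecordError, ValidationError

AUTISM = "autism"
NEUROTYPICAL = "neurotypical"
CLASS_LABELS = (AUTISM, NEUROTYPICAL)


@dataclass(frozen=True)
class VideoRecord:
    """A rated video and its ground-truth binary class."""

    video_id: str
    true_class: str
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.true_class not in CLASS_LABELS:
            raise ValidationError(
                f"video {self.video_id!r}: true_class must be one of "
                f"{CLASS_LABELS}, got {self.true_class!r}"
            )
        if self.duration_s is not None and self.duration_s < 0:
            raise ValidationError(f"video {self.video_id!r}: negative duration")


@dataclass(frozen=True)
class WorkerResponse:
    """One worker x video rating event.

    ``warned`` records the interactive minimum-time prompt; when it is
    false no revision fields may be present. ``t2_s`` is the additional
    time spent after the warning, absent if the worker never reopened the
    task.
    """

    worker_id: str
    video_id: str
    attempt: int
    answers: tuple[int, ...]
    t1_s: float
    warned: bool = False
    revised_answers: tuple[int, ...] | None = None
    t2_s: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "answers", tuple(int(a) for a in self.answers))
        if self.revised_answers is not None:
            object.__setattr__(
                self, "revised_answers", tuple(int(a) for a in self.revised_answers)
            )
        if self.attempt < 1:
            raise ValidationError(f"{self._key()}: attempt must be >= 1")
        if self.t1_s < 0:
            raise ValidationError(f"{self._key()}: negative t1_s")
        if self.t2_s is not None and self.t2_s < 0:
            raise ValidationError(f"{self._key()}: negative t2_s")
        if not self.warned and (self.revised_answers is not None or self.t2_s is not None):
            raise ValidationError(
                f"{self._key()}: revision fields present but warned is false"
            )

    def _key(self) -> tuple[str, str, int]:
        return (self.worker_id, self.video_id, self.attempt)


def validate_answer_vector(
    answers: Sequence[int],
    levels: Sequence[int],
    context: str = "answer vector",
) -> None:
    """Check an answer vector against the per-question level counts.

    Raises :class:`ValidationError` naming the offending question on the
    first out-of-range code, and on a length mismatch.
    """
    if len(answers) != len(levels):
        raise ValidationError(
            f"{context}: has {len(answers)} answers, expected {len(levels)}"
        )
    for j, (a, L) in enumerate(zip(answers, levels), start=1):
        if not 0 <= a <= L - 1:
            raise ValidationError(
                f"{context}: question {j} has code {a}, valid range is 0..{L - 1}"
            )


def validate_responses(
    responses: Iterable[WorkerResponse], config: StudyConfig
) -> list[WorkerResponse]:
    """Validate a response collection against a study config.

    Checks answer ranges for both original and revised vectors, enforces
    uniqueness of (worker_id, video_id, attempt), and cross-checks the
    recorded ``warned`` flag against ``t1_s < T_s`` — the warning was an
    interactive platform event, so the data carry it explicitly, but an
    inconsistent flag is reported via :mod:`warnings`.

    Returns the validated records as a list.
    """
    seen: set[tuple[str, str, int]] = set()
    out: list[WorkerResponse] = []
    inconsistent: list[tuple[str, str, int]] = []
    for r in responses:
        key = r._key()
        if key in seen:
            raise DuplicateRecordError(f"duplicate (worker, video, attempt) record {key}")
        seen.add(key)
        ctx = f"worker {r.worker_id!r}, video {r.video_id!r}, attempt {r.attempt}"
        validate_answer_vector(r.answers, config.levels, ctx)
        if r.revised_answers is not None:
            validate_answer_vector(r.revised_answers, config.levels, ctx + " (revised)")
        if r.warned and r.t1_s >= config.T_s:
            inconsistent.append(key)
        out.append(r)
    if inconsistent:
        warnings.warn(
            f"{len(inconsistent)} warned record(s) have t1_s >= T_s={config.T_s}: "
            f"{inconsistent[:5]}",
            stacklevel=2,
        )
    return out
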