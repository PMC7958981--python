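"""Study-level configuration shared across the pipeline.

A :class:`StudyConfig` pins the task mechanics (question count, per-question
answer levels, the minimum-time warning threshold) together with the
analysis gates (minimum videos per worker for metric computation, minimum
data points per worker for correlation analysis) and the penalized-time
weighting constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of a video-rating study.

    Parameters
    ----------
    T_s
        Warning threshold in seconds: a rating completed in less than
        ``T_s`` triggers a revision request. Default 120 s (2 minutes).
    M
        Number of multiple-choice questions per video rating task.
    levels
        Per-question count of ordinal answer levels; answer codes for
        question ``j`` are the integers ``0 .. levels[j] - 1``. Defaults
        to four levels for every question.
    c
        Weighting constant balancing the revision-distance term of the
        penalized-time metric against its time term.
    min_videos_metrics
        Workers must have rated at least this many distinct videos
        (first attempt) for their metrics to be computed.
    min_points_analysis
        A worker's mean value enters a correlation analysis only if it
        aggregates at least this many underlying data points.
    pcc_threshold
        Probability threshold for hard class assignment.
    seed
        Default seed recorded in derived reports.
    """

    T_s: float = 120.0
    M: int = 13
    levels: tuple[int, ...] = field(default=None)  # type: ignore[assignment]
    c: float = 1.0
    min_videos_metrics: int = 10
    min_points_analysis: int = 5
    pcc_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels is None:
            object.__setattr__(self, "levels", (4,) * self.M)
        else:
            object.__setattr__(self, "levels", tuple(int(v) for v in self.levels))
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if len(self.levels) != self.M:
            raise ValueError(f"levels has length {len(self.levels)}, expected M={self.M}")
        if any(v < 2 for v in self.levels):
            raise ValueError("every question needs at least 2 answer levels")
        if self.T_s <= 0:
            raise ValueError("T_s must be positive")
        if not 0 < self.pcc_threshold < 1:
            raise ValueError("pcc_threshold must be in (0, 1)")
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.min_videos_metrics < 2:
            raise ValueError("min_videos_metrics must be >= 2")


def save_study_config(config: StudyConfig, path: str | Path) -> None:
    """Write a config as a flat YAML key-value document."""
    doc = asdict(config)
    doc["levels"] = list(config.levels)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_study_config(path: str | Path) -> StudyConfig:
    """Read a config written by :func:`save_study_config`."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return StudyConfig(**doc)
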