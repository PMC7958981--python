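"""Delimited-text I/O for responses, videos and classifier specs.

The canonical interchange format is UTF-8 CSV with a header row:

* responses: ``worker_id, video_id, attempt, t1_s, warned, t2_s, a1..aM,
  r1..rM`` — one row per (worker, video, attempt); revision columns
  ``r1..rM`` and ``t2_s`` are empty unless the rating was warned and
  revised.
* videos: ``video_id, true_class, duration_s`` (duration optional).
* classifier spec and study config: flat YAML key-value documents.

Ingestion never silently drops rows: malformed input raises a typed error
naming the offending column or record.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .classifier import ClassifierSpec
from .config import StudyConfig
from .data_model import CLASS_LABELS, VideoRecord, WorkerResponse, validate_responses
from .exceptions import FormatError, ValidationError

_BOOL_STRINGS = {
    "true": True, "false": False, "1": True, "0": False, "yes": True, "no": False,
}


def _answer_columns(M: int) -> tuple[list[str], list[str]]:
    return [f"a{j}" for j in range(1, M + 1)], [f"r{j}" for j in range(1, M + 1)]


def _parse_bool(value, context: str) -> bool:
    if isinstance(value, bool):
        return value
    try:
        return _BOOL_STRINGS[str(value).strip().lower()]
    except KeyError:
        raise ValidationError(f"{context}: cannot parse boolean {value!r}") from None


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def read_responses(path: str | Path, config: StudyConfig) -> list[WorkerResponse]:
    """Read and validate a worker-response CSV.

    Every row becomes a :class:`WorkerResponse` satisfying its invariants;
    answer codes are checked against ``config.levels``. A partially filled
    revision block (some of ``r1..rM`` empty, some not) is rejected.
    """
    a_cols, r_cols = _answer_columns(config.M)
    required = ["worker_id", "video_id", "attempt", "t1_s", "warned", "t2_s"] + a_cols + r_cols
    df = pd.read_csv(path, dtype={"worker_id": str, "video_id": str}, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records: list[WorkerResponse] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        ctx = f"worker {d['worker_id']!r}, video {d['video_id']!r}, attempt {d['attempt']}"
        warned = _parse_bool(d["warned"], ctx)
        for c in a_cols:
            if _is_missing(d[c]):
                raise ValidationError(f"{ctx}: empty answer cell {c}")
        answers = tuple(int(d[c]) for c in a_cols)
        rev_missing = [_is_missing(d[c]) for c in r_cols]
        if all(rev_missing):
            revised = None
        elif any(rev_missing):
            raise ValidationError(f"{ctx}: partially filled revision answers")
        else:
            revised = tuple(int(d[c]) for c in r_cols)
        t2 = None if _is_missing(d["t2_s"]) else float(d["t2_s"])
        records.append(
            WorkerResponse(
                worker_id=str(d["worker_id"]),
                video_id=str(d["video_id"]),
                attempt=int(d["attempt"]),
                answers=answers,
                t1_s=float(d["t1_s"]),
                warned=warned,
                revised_answers=revised,
                t2_s=t2,
            )
        )
    return validate_responses(records, config)


def write_responses(
    records: Iterable[WorkerResponse],
    path: str | Path,
    config: StudyConfig | None = None,
) -> None:
    """Write responses to CSV, readable back by :func:`read_responses`.

    Absent fields are serialized as empty cells. ``config`` supplies the
    question count for an empty record set; otherwise it is inferred.
    """
    records = list(records)
    if records:
        M = len(records[0].answers)
    elif config is not None:
        M = config.M
    else:
        raise ValueError("cannot infer question count for empty record set without config")
    a_cols, r_cols = _answer_columns(M)
    rows = []
    for r in records:
        row = {
            "worker_id": r.worker_id,
            "video_id": r.video_id,
            "attempt": r.attempt,
            "t1_s": r.t1_s,
            "warned": r.warned,
            "t2_s": r.t2_s if r.t2_s is not None else "",
        }
        for j, c in enumerate(a_cols):
            row[c] = r.answers[j]
        for j, c in enumerate(r_cols):
            row[c] = r.revised_answers[j] if r.revised_answers is not None else ""
        rows.append(row)
    cols = ["worker_id", "video_id", "attempt", "t1_s", "warned", "t2_s"] + a_cols + r_cols
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_videos(path: str | Path) -> list[VideoRecord]:
    """Read a video table; class labels restricted to the two allowed values."""
    df = pd.read_csv(path, dtype={"video_id": str}, float_precision="round_trip")
    missing = [c for c in ("video_id", "true_class") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out: list[VideoRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        label = str(d["true_class"]).strip()
        if label not in CLASS_LABELS:
            raise ValidationError(
                f"video {d['video_id']!r}: unknown class label {label!r}"
            )
        dur = d.get("duration_s")
        out.append(
            VideoRecord(
                video_id=str(d["video_id"]),
                true_class=label,
                duration_s=None if _is_missing(dur) else float(dur),
            )
        )
    return out


def write_videos(videos: Iterable[VideoRecord], path: str | Path) -> None:
    rows = [
        {
            "video_id": v.video_id,
            "true_class": v.true_class,
            "duration_s": v.duration_s if v.duration_s is not None else "",
        }
        for v in videos
    ]
    pd.DataFrame(rows, columns=["video_id", "true_class", "duration_s"]).to_csv(
        path, index=False
    )


def read_classifier_spec(path: str | Path) -> ClassifierSpec:
    """Read a classifier spec (weights, intercept, positive_class) from YAML."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "weights" not in doc or "intercept" not in doc:
        raise FormatError(f"{path}: expected a mapping with 'weights' and 'intercept'")
    return ClassifierSpec(
        weights=tuple(float(w) for w in doc["weights"]),
        intercept=float(doc["intercept"]),
        positive_class=doc.get("positive_class", "autism"),
    )


def write_classifier_spec(spec: ClassifierSpec, path: str | Path) -> None:
    doc = {
        "weights": [float(w) for w in spec.weights],
        "intercept": float(spec.intercept),
        "positive_class": spec.positive_class,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_pcc(path: str | Path) -> pd.DataFrame:
    """Read a per-response PCC table written by ``score_responses(...)``."""
    df = pd.read_csv(path, dtype={"worker_id": str, "video_id": str}, float_precision="round_trip")
    missing = [c for c in ("worker_id", "video_id", "attempt", "p_autism", "pcc") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_metrics(path: str | Path) -> pd.DataFrame:
    """Read a worker-metrics table written by ``metrics_frame(...).to_csv``."""
    df = pd.read_csv(path, dtype={"worker_id": str}, float_precision="round_trip")
    if "worker_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'worker_id'")
    return df
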