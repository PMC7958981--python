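"""Exception hierarchy for crowdtrust."""


class CrowdTrustError(Exception):
    """Base class for all crowdtrust errors."""


class FormatError(CrowdTrustError):
    """A tabular input file is structurally malformed (e.g. missing columns)."""


class ValidationError(CrowdTrustError):
    """A record violates a data-model invariant."""


class DuplicateRecordError(ValidationError):
    """Two rows share the same (worker_id, video_id, attempt) key."""


class DimensionError(CrowdTrustError, ValueError):
    """Vector lengths disagree (answer vector vs. weights, or vs. each other)."""


class UndefinedMetricError(CrowdTrustError):
    """A per-worker metric's precondition is not met (e.g. no retest videos).

    Aggregate operations catch this and record the metric as absent rather
    than failing the whole cohort.
    """


class InsufficientDataError(CrowdTrustError):
    """Too few eligible workers (or samples) for a statistical operation."""


class ConstantInputError(InsufficientDataError):
    """A correlation input has no variance, so r is undefined."""


class ContaminationError(CrowdTrustError):
    """Train and test cohorts share worker ids in a cross-cohort evaluation."""


class GenerationError(CrowdTrustError):
    """The synthetic generator could not satisfy its constraints."""
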