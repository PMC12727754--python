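"""Exception hierarchy for fitkit.

Every error raised by the library derives from :class:`FitkitError`, so callers
can catch a single base class at pipeline boundaries (e.g. the CLI).
"""


class FitkitError(Exception):
    """Base class for all fitkit errors."""


class SchemaError(FitkitError):
    """A tabular input is missing a required column or has a bad header."""


class IntegrityError(FitkitError):
    """Data violates an identity constraint (duplicate ids, cross-question sid)."""


class PartitionError(FitkitError):
    """A question bank cannot be split into the requested number of sets."""


class ParseError(FitkitError):
    """A row or a judge response could not be parsed."""


class ValidationError(FitkitError):
    """An input record violates a documented invariant."""


class JudgeError(FitkitError):
    """A judge gave no parseable verdict after the configured retries."""


class SchedulingError(FitkitError):
    """A rater plan cannot be built (too few candidates, missing sanity pair)."""


class QCError(FitkitError):
    """A judgment block is missing its sanity-check judgment."""


class BatchingError(FitkitError):
    """A rating batch exceeds the allowed size."""


class DegenerateDataError(FitkitError):
    """A statistic is undefined on the given data (zero variance, too few points)."""


class NoSolutionError(FitkitError):
    """A search (e.g. minimal sample size) has no attainable answer."""
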