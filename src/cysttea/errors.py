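"""Exception hierarchy for the cyst-tea pipeline.

Every error raised by the package derives from :class:`CystTeaError` so
callers can catch pipeline failures without masking programming errors.
Where a builtin category fits (value range, missing key), the class also
derives from the corresponding builtin.
"""


class CystTeaError(Exception):
    """Base class for all cyst-tea errors."""


class FormatError(CystTeaError, ValueError):
    """A file does not conform to the expected on-disk schema."""


class IntegrityError(CystTeaError, ValueError):
    """Duplicate or mutually conflicting records in an input."""


class VocabularyError(CystTeaError, ValueError):
    """A categorical cell holds a value outside the allowed vocabulary."""


class RangeError(CystTeaError, ValueError):
    """A numeric value lies outside its permitted range."""


class UsageError(CystTeaError, ValueError):
    """An operation was invoked on degenerate input (e.g. an empty list)."""


class EmptyLibraryError(CystTeaError, ValueError):
    """Reference construction produced no tissue sets at all."""


class SampleLookupError(CystTeaError, KeyError):
    """A requested sample label is absent from the intensity table."""


class DataSufficiencyError(CystTeaError, ValueError):
    """Too few detected proteins/points to run the requested statistic."""


class DomainError(CystTeaError, ValueError):
    """Hypergeometric arguments violate N >= M, N >= n or 0 <= k <= min(n, M)."""


class ConsistencyError(CystTeaError, ValueError):
    """Inputs that must share provenance (query/universe/records) disagree."""


class ConfigurationError(CystTeaError, ValueError):
    """Synthetic-generator parameters are mutually infeasible."""


class DegenerateInputError(CystTeaError, ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""
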