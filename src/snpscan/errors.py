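"""Exception hierarchy shared across the package."""


class SnpScanError(Exception):
    """Base class for all package errors."""


class ParseError(SnpScanError):
    """A file could not be parsed (malformed field, bad header, ...)."""


class ValidationError(SnpScanError):
    """An input violates a documented invariant."""


class DuplicateRecordError(ValidationError):
    """The same key appears more than once where uniqueness is required."""


class MissingRecordError(ValidationError):
    """An expected (marker, sample) combination is absent."""


class DegenerateGeneError(SnpScanError):
    """A gene (or region) has too few usable observations for testing."""


class UndefinedTestError(SnpScanError):
    """Both group variances are zero; the variance-ratio test is undefined."""


class ConsistencyError(SnpScanError):
    """Two inputs that must agree (e.g. truth vs. results) do not."""
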