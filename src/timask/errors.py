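"""Exception hierarchy.

Every reader/operation failure raises a subclass of :class:`TimaskError`
carrying enough context (column, group key, material) to locate the
offending input.
"""


class TimaskError(Exception):
    """Base class for all package errors."""


class FormatError(TimaskError):
    """A file does not have the expected structure (e.g. a missing column)."""


class ValidationError(TimaskError):
    """A row or group violates a domain-type invariant."""


class ParameterError(TimaskError, ValueError):
    """An operation was called with an invalid tunable (window, threshold, k)."""


class UsageError(TimaskError):
    """Operations called out of order or on unsuitable inputs."""


class FlatCurveError(ValidationError):
    """No sample of a curve ever exceeds the onset threshold."""
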