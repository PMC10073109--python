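"""Exception hierarchy for the pipeline.

``FormatError`` signals a malformed input file (wrong columns, duplicate
identifiers, unparseable cells); ``ValidationError`` signals structurally
well-formed data that violates a domain invariant (a beta value outside
[0, 1], a negative intensity); ``ConfigurationError`` signals a bad
parameter or group label.  All derive from ``MethrevError`` so callers can
catch pipeline failures in one clause, and from ``ValueError`` so they
behave conventionally.
"""


class MethrevError(ValueError):
    """Base class for all errors raised by this package."""


class FormatError(MethrevError):
    """An input file does not conform to its expected tabular format."""


class ValidationError(MethrevError):
    """Data violates a domain invariant (range, shape, uniqueness)."""


class ConfigurationError(MethrevError):
    """A parameter, threshold, or group label is invalid."""
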