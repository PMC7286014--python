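"""Exception hierarchy for sfdose.

All exceptions derive from :class:`SfdoseError` so callers can catch the
package's failures with a single except clause; parse/validation errors keep
enough context (line numbers, curve keys, sides) to point at the offending
input.
"""


class SfdoseError(Exception):
    """Base class for all sfdose errors."""


class ScanParseError(SfdoseError):
    """A scan file violates the text dialect (names the offending line)."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(SfdoseError, ValueError):
    """A domain object violates one of its invariants."""


class ShapeError(SfdoseError):
    """A profile does not have the expected geometric shape.

    Raised e.g. when a level is crossed zero or more than one time on one
    side of the peak; the message names the side.
    """


class RangeError(SfdoseError, ValueError):
    """A query lies outside the tabulated or scanned range."""


class DegenerateInputError(SfdoseError, ValueError):
    """Input is formally valid but has no usable signal (all-zero curve...)."""


class ConsistencyError(SfdoseError, ValueError):
    """Two objects that must describe the same field/geometry do not."""


class ConfigurationError(SfdoseError, ValueError):
    """A scenario or pipeline configuration is incomplete or contradictory."""
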