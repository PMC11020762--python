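"""Exception hierarchy shared across the package."""


class RectileError(Exception):
    """Base class for all package errors."""


class FormatError(RectileError):
    """A file could not be parsed as the expected format."""


class SchemaError(RectileError):
    """Required bands, columns or classes are missing."""


class ParameterError(RectileError, ValueError):
    """A parameter violates its precondition."""


class ExtentError(RectileError):
    """A point or window falls outside the spatial/temporal extent."""


class AssemblyError(RectileError):
    """A feature stack could not be assembled as specified."""


class DegenerateCurveError(RectileError):
    """A curve is constant where a non-constant curve is required."""
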