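"""Exception hierarchy shared across the package."""


class RetFDCError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RetFDCError, ValueError):
    """A parameter is outside its documented domain."""


class FormatError(RetFDCError, ValueError):
    """An input array or file does not have the expected layout."""


class GeometryError(RetFDCError, ValueError):
    """Scan or crop geometry does not fit inside the image frame."""


class ConstantSeriesError(RetFDCError, ValueError):
    """A 1D series is constant, so its curve length (and FD) is undefined."""


class DegenerateInputError(RetFDCError, ValueError):
    """Input is too degenerate for the requested estimator (e.g. empty foreground)."""
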