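"""Exception hierarchy for plexflow.

All errors raised by the library derive from :class:`PlexflowError` so that
pipeline code can isolate per-network failures with a single except clause.
"""


class PlexflowError(Exception):
    """Base class for all plexflow errors."""


class FormatError(PlexflowError):
    """Malformed input file (hoc or tabular). Carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GeometryError(PlexflowError):
    """Invalid geometry (degenerate section, non-positive diameter/length)."""


class EmptyInputError(FormatError):
    """Input file contains no usable content."""


class ReferentialIntegrityError(PlexflowError):
    """A segment references a node that does not exist."""


class ConfigurationError(PlexflowError):
    """Invalid parameter set or boundary policy outcome (e.g. no inlets)."""


class DegenerateNetworkError(PlexflowError):
    """Network cannot support a well-posed solve (singular system, no perfusion)."""


class UndefinedMetricError(PlexflowError):
    """A metric is requested on an input for which it is undefined."""


class ConvergenceError(PlexflowError):
    """Iterative solver exhausted its iteration budget."""
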