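"""Exception hierarchy shared across the package.

Each class maps to a distinct CLI exit code (see :mod:`repliorg.cli`).
"""


class ReplorgError(Exception):
    """Base class for package-specific errors."""


class ConfigError(ReplorgError, ValueError):
    """Invalid configuration value or window/model specification."""


class ParseError(ReplorgError, ValueError):
    """Malformed interchange file; message names file, line and rule."""


class CoordinateError(ReplorgError, ValueError):
    """Position or gene coordinates outside the circular chromosome."""


class OrderingError(ReplorgError, ValueError):
    """Gene list not sorted by start coordinate where order is required."""


class FilteredInputError(ReplorgError, ValueError):
    """A spot that should have been removed by filtering reached a ratio op."""


class UndefinedCorrelationError(ReplorgError, ValueError):
    """Zero rank variance: a rank correlation is undefined."""


class GenerationError(ReplorgError, ValueError):
    """Synthetic-data parameters leave no room to place genes."""


class PipelineError(ReplorgError, RuntimeError):
    """A pipeline stage failed; message carries the stage label."""
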