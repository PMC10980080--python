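"""Exception hierarchy for era3d.

All user-facing failures derive from :class:`Era3dError` so the CLI can map
them to exit code 1 (user error) while anything else is an internal error.
"""


class Era3dError(Exception):
    """Base class for expected, user-facing errors."""


class ConfigError(Era3dError):
    """Invalid configuration (bad parameter values, empty taxonomy, ...)."""


class InputError(Era3dError):
    """Invalid input data (genome mismatch, out-of-range phylostratum, ...)."""


class ParseError(InputError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SizingError(Era3dError):
    """A synthetic genome or sampling region is too small for the request."""


class NormalizationError(Era3dError):
    """Median-of-ratios normalization impossible (no all-nonzero gene)."""


class ConstantInputError(Era3dError):
    """Correlation undefined because an input vector is constant."""


class TransformError(Era3dError):
    """A display transform is undefined for the given values (e.g. all-zero)."""


class EmptyComparisonError(Era3dError):
    """Two age assignments share no genes, so no comparison is possible."""
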