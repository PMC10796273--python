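"""Exception hierarchy shared across the package.

Every error raised by qbetkit derives from :class:`QbetError` so pipeline
code can distinguish our failures from genuine bugs.
"""


class QbetError(Exception):
    """Base class for all qbetkit errors."""


class InputError(QbetError, ValueError):
    """Invalid user-supplied value (bad range, wrong unit, degenerate input)."""


class ConfigurationError(QbetError):
    """A required configuration value is missing or inconsistent."""


class SchemaError(QbetError):
    """A tabular input does not match the expected column schema."""


class ParseError(QbetError):
    """A cell in a tabular input could not be converted to its declared type."""


class DiscretizationError(QbetError):
    """The finite-difference grid violates the explicit-scheme stability bound."""


class NoPeakError(QbetError):
    """No peak exceeding the noise floor was found on a voltammogram branch."""

    def __init__(self, branch: str, message: str | None = None):
        self.branch = branch
        super().__init__(message or f"no peak detected on the {branch} branch")


class FitError(QbetError):
    """A regression has too few usable points or a degenerate design."""


class AnalysisError(QbetError):
    """A composite analysis stage cannot produce a result."""
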