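"""Exception and warning hierarchy."""

from __future__ import annotations


class AstamixError(Exception):
    """Base class for all package-specific errors."""


class InputError(AstamixError, ValueError):
    """A caller-supplied value violates a precondition."""


class DegenerateDesignError(AstamixError):
    """Calibration design cannot identify a line (fewer than two distinct
    concentrations)."""


class ConfigurationError(AstamixError):
    """Inconsistent model configuration (e.g. duplicate source/channel curve)."""


class IdentifiabilityError(AstamixError):
    """The mixture system is rank deficient; the named sources are colinear."""

    def __init__(self, message: str, colinear_sources: tuple[str, ...] = ()):
        super().__init__(message)
        self.colinear_sources = colinear_sources


class UndefinedRatioError(AstamixError, ZeroDivisionError):
    """Area ratio requested against a zero-area denominator channel."""


class ParseError(AstamixError):
    """A delimited-text input failed validation; names the offending row."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = f"{path or '<input>'}:{line}" if line is not None else (path or "<input>")
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.line = line


class CalibrationRangeWarning(UserWarning):
    """Prediction requested outside the concentration range of the fit."""


class CalibrationQualityWarning(UserWarning):
    """Calibration r² fell below the QC threshold."""


class AnalyticalRangeWarning(UserWarning):
    """Solved concentration outside the model's analytical range."""


class ResolutionWarning(UserWarning):
    """Simulated chromatographic peaks too close to be baseline resolved."""
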