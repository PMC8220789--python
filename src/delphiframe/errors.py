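"""Exception hierarchy shared across the pipeline stages."""


class DelphiFrameError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DelphiFrameError, ValueError):
    """An invalid generator or run configuration (bad thresholds, non-PSD
    correlation block, inverted cutpoints, ...)."""


class ValidationError(DelphiFrameError, ValueError):
    """Structurally invalid data: a malformed codebook, an out-of-range
    Likert cell, an unknown column. Carries every violation found."""

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class InsufficientDataError(DelphiFrameError, ValueError):
    """Too few non-missing observations for the requested statistic."""

    def __init__(self, message, criterion=None):
        self.criterion = criterion
        super().__init__(message)


class DegenerateMarginalError(DelphiFrameError, ValueError):
    """A variable with a single observed category; the polychoric
    correlation is undefined."""
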