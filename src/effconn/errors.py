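"""Exception hierarchy shared across the package."""


class EffconnError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EffconnError, ValueError):
    """Input violates a documented precondition."""


class FormatError(EffconnError, ValueError):
    """A file is readable but its contents do not match the expected format."""


class SingularFitError(EffconnError, ValueError):
    """The least-squares regressor matrix is rank deficient."""

    def __init__(self, message: str, channels: list[str] | None = None):
        super().__init__(message)
        self.channels = channels or []


class ConfigurationError(EffconnError, ValueError):
    """A backend or option is misconfigured."""


class UndefinedMetricError(EffconnError, ZeroDivisionError):
    """A performance metric has a zero denominator."""
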