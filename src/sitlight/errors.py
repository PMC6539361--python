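"""Exception hierarchy shared across the package."""


class SitlightError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SitlightError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(SitlightError):
    """Not enough data to compute the requested quantity."""


class CalibrationError(SitlightError):
    """A calibration run produced an unusable HRV range."""


class CalibrationRequiredError(SitlightError):
    """An operation needs a per-user HRV calibration that was not supplied."""


class TrainingFailedError(SitlightError):
    """Levenberg-Marquardt could not make progress (singular normal equations)."""


class InvalidModelError(SitlightError):
    """Model dimensions are inconsistent with the input."""


class ParseError(SitlightError):
    """A CSV/JSON input file is malformed."""


class ValidationError(SitlightError):
    """Parsed data violates a schema invariant (e.g. non-monotone time)."""


class ConfigError(SitlightError):
    """Configuration file contains unknown keys or out-of-range values."""
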