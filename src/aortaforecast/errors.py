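"""Exception hierarchy."""


class AortaForecastError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AortaForecastError):
    """Invalid generator or run configuration."""


class ParameterError(AortaForecastError):
    """Model parameters violate their constraints (PD-ness, |rho|<1, ...)."""


class SpecificationError(AortaForecastError):
    """Model specification inconsistent with the data or parameters."""


class DataError(AortaForecastError):
    """Malformed or invalid input data."""


class RequestError(AortaForecastError):
    """Invalid forecast request."""


class FitError(AortaForecastError):
    """Estimation failed to converge."""
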