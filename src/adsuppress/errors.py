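"""Exception types shared across the package."""


class AdsuppressError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AdsuppressError, ValueError):
    """A generator or estimator parameter is outside its admissible range."""


class ValidationError(AdsuppressError, ValueError):
    """A recording bundle or event timeline failed validation."""


class FitError(AdsuppressError, RuntimeError):
    """A model fit could not be carried out on the given data."""
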