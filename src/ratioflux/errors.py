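"""Exception hierarchy shared across the package."""


class RatioFluxError(Exception):
    """Base class for all ratioflux errors."""


class FormatError(RatioFluxError):
    """A file does not conform to the expected dialect (e.g. missing timestamp column)."""


class IntegrityError(RatioFluxError):
    """Structurally valid input violates an integrity constraint (e.g. duplicate timestamps)."""


class ValidationError(RatioFluxError):
    """A value is outside its documented domain."""


class ConfigurationError(RatioFluxError):
    """A requested option cannot be honoured with the available inputs."""


class ParameterError(RatioFluxError):
    """An operation was called with an invalid parameter value."""


class FitError(RatioFluxError):
    """A model fit is underdetermined or otherwise impossible."""
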