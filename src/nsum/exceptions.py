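"""Exception hierarchy for the nsum package."""


class NSUMError(Exception):
    """Base class for all package errors."""


class ValidationError(NSUMError, ValueError):
    """Invalid input data or configuration."""


class FrameValidationError(ValidationError):
    """A study-frame config violates a frame invariant."""


class DesignError(ValidationError):
    """Degenerate or out-of-range randomized-response design."""


class BootstrapError(NSUMError, RuntimeError):
    """Bootstrap procedure could not complete (e.g. statistic failed on too many resamples)."""
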