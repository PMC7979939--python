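"""Exception hierarchy shared across the pipeline stages."""


class ThzMarginError(Exception):
    """Base class for all package errors."""


class ValidationError(ThzMarginError):
    """A configuration or argument violated a stage precondition."""


class DegenerateMediaError(ThzMarginError):
    """Raised when an interface coefficient is undefined (n̂_a + n̂_b = 0)."""


class EmptyBandError(ThzMarginError):
    """No frequency survived the reference SNR floor."""


class EmptyRegionError(ThzMarginError):
    """A contour level or support selection produced an empty region."""


class RegistrationError(ThzMarginError):
    """Registration stage failure (no closed isoline, undefined correlation...)."""


class EvaluationError(ThzMarginError):
    """Evaluation stage failure, e.g. the evaluable region is empty."""
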