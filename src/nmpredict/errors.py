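"""Exception hierarchy shared across the pipeline stages."""


class NmPredictError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(NmPredictError):
    """An input record violates a precondition (empty sequence, bad frame, ...)."""


class DegenerateInputError(NmPredictError):
    """Input is syntactically valid but carries no usable signal
    (all-zero counts, a constant feature column)."""


class NumericalFailureError(NmPredictError):
    """A numerical routine failed despite regularization."""


class AmbiguousModelError(NmPredictError):
    """A fitted model does not admit the requested decision (exact tie)."""


class ConfigError(NmPredictError):
    """A configuration value is out of range or internally inconsistent."""
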