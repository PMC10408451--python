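"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`InrfqaError` so that
callers (and the CLI) can map failures to exit codes without string matching.
"""


class InrfqaError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(InrfqaError, ValueError):
    """A parameter value violates its documented precondition."""


class InvalidInputError(InrfqaError, ValueError):
    """Input data (image, video, CSV row) is malformed or unsupported."""


class ShapeMismatchError(InrfqaError, ValueError):
    """Reference and distorted inputs do not share the same geometry."""


class UnsupportedSizeError(InrfqaError, ValueError):
    """A kernel is too large for the image it is applied to."""


class ConfigurationError(InrfqaError, ValueError):
    """Missing or inconsistent run configuration (e.g. raw-video geometry)."""


class UndefinedCorrelationError(InrfqaError, ValueError):
    """A correlation is requested on a constant (zero-variance) vector."""


class FitFailureError(InrfqaError, RuntimeError):
    """The logistic fit did not converge.

    Carries the initialization used so the failure is reproducible.
    """

    def __init__(self, message, init=None):
        super().__init__(message)
        self.init = init
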