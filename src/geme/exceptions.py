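"""Exception hierarchy for the geme package."""


class GemeError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(GemeError, ValueError):
    """An input violated a documented precondition or invariant."""


class DegenerateEmbeddingError(GemeError):
    """The centered Gram matrix carries no positive spectral mass to embed."""


class ZeroVolumeWindowError(GemeError):
    """The observation window collapsed to zero volume on some axis."""


class UnsupportedCorrectionError(GemeError):
    """The requested edge correction is not defined for this dimension."""


class DegenerateNodeError(GemeError):
    """A node's time series has zero variance; its correlations are undefined."""
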