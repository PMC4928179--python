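"""Exception hierarchy for saxsflex."""


class SaxsFlexError(Exception):
    """Base class for all saxsflex errors."""


class MalformedProfileError(SaxsFlexError):
    """A scattering file could not be parsed into a usable profile."""


class NoGuinierRegionError(SaxsFlexError):
    """The low-q data show no decay, so no Guinier region exists."""


class InsufficientDataError(SaxsFlexError):
    """Too few data points for the requested analysis."""


class CoverageError(SaxsFlexError):
    """The Rg quadrature grid misses too much probability mass."""


class FitFailureError(SaxsFlexError):
    """Every optimizer start failed to converge.

    Carries per-start diagnostics in ``self.diagnostics``.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
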