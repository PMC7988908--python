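"""Exception hierarchy shared across atavlite modules."""


class AtavLiteError(Exception):
    """Base class for all atavlite-specific errors."""


class ValidationError(AtavLiteError, ValueError):
    """Invalid argument or out-of-contract input value."""


class ParseError(AtavLiteError, ValueError):
    """Malformed serialized data (RLE string, depth file, PED row...)."""


class IntegrityError(AtavLiteError):
    """Stored or supplied data contradicts itself (e.g. REF/reference mismatch)."""


class WindowExhaustedError(AtavLiteError):
    """Left-alignment ran off the supplied reference window."""


class ConfigurationError(AtavLiteError):
    """An analysis configuration references data that is not available."""


class ConfigOrderError(ConfigurationError):
    """A config pair violates the stricter-than partial order required by collapsing-lite."""


class GeneLookupError(AtavLiteError, KeyError):
    """Unknown gene symbol; carries near matches."""

    def __init__(self, symbol, suggestions=()):
        self.symbol = symbol
        self.suggestions = list(suggestions)
        msg = f"unknown gene symbol {symbol!r}"
        if self.suggestions:
            msg += f"; did you mean: {', '.join(self.suggestions)}?"
        super().__init__(msg)

    def __str__(self):  # KeyError quotes its arg by default
        return self.args[0]


class AnnotationError(AtavLiteError):
    """Annotation table violates its schema (duplicate key, missing column...)."""


class PedCycleError(AtavLiteError):
    """An individual in a PED file is listed as its own ancestor."""


class MultiSampleVCFError(AtavLiteError):
    """The store ingests single-sample VCFs only."""


class ConvergenceError(AtavLiteError):
    """Iterative fit did not converge; carries the last iterate."""

    def __init__(self, message, beta=None, grad_norm=None, n_iter=None):
        super().__init__(message)
        self.beta = beta
        self.grad_norm = grad_norm
        self.n_iter = n_iter
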