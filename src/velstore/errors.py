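"""Exception hierarchy for the velocity-storage model."""


class VelstoreError(Exception):
    """Base class for all velstore errors."""


class InvalidParameterError(VelstoreError, ValueError):
    """A model or operation parameter is outside its valid domain."""


class DegenerateEigenstructureError(VelstoreError, ArithmeticError):
    """Coincident decay rates with nonzero coupling: the closed-form
    eigenvector divides by (h_yy - h_aa) ~ 0 and is not meaningful."""


class UndefinedRatioError(VelstoreError, ZeroDivisionError):
    """A percent-change ratio was requested against a zero baseline."""


class FitInputError(VelstoreError, ValueError):
    """The data or configuration handed to the fitter is unusable."""
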