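"""Exception hierarchy.

All failures that callers may want to catch programmatically derive from
:class:`MeanMatchError`; plain ``ValueError`` is reserved for argument
misuse (wrong shapes, unknown option names).
"""


class MeanMatchError(Exception):
    """Base class for meanmatch failures."""


class SingularDesignError(MeanMatchError):
    """Design matrix is rank deficient.

    ``columns`` lists the 0-based indices of columns implicated in the
    collinearity (those beyond the numerical rank under pivoted QR).
    """

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = tuple(columns) if columns is not None else ()


class InsufficientDataError(MeanMatchError):
    """Too few observed cases to fit the imputation model."""


class EmptyDonorPoolError(MeanMatchError):
    """A caliper donor pool came up empty; caller decides the fallback."""


class ConstrainedSamplingError(MeanMatchError):
    """Constrained donor sampling is infeasible or exhausted."""


class CalibrationError(MeanMatchError):
    """Missingness-mechanism calibration failed to converge."""


class DataFormatError(MeanMatchError):
    """A delimited-text table violated the expected format."""
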