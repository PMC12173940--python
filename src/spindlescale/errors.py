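"""Exception hierarchy used across the package.

All input-validation failures raise :class:`ValidationError` (a ``ValueError``)
so callers can distinguish bad inputs from numerical problems, which raise
:class:`FitError` or :class:`DegenerateDataError`.
"""


class SpindleScaleError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SpindleScaleError, ValueError):
    """An input violates a documented precondition or record invariant."""


class DegenerateDataError(SpindleScaleError, ValueError):
    """Data are formally valid but make the requested statistic undefined.

    Examples: a constant vector passed to a rank correlation, a zero-range
    trace passed to min-max normalization, zero pooled variance with unequal
    means in a two-group comparison.
    """


class FitError(SpindleScaleError, RuntimeError):
    """A nonlinear fit failed to converge or produced an inadmissible optimum.

    Carries a ``diagnostics`` dict with the initialization(s) tried and the
    solver message, so failures are debuggable rather than silent.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
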