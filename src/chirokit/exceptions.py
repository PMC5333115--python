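"""Exception hierarchy for chirokit.

All package errors derive from :class:`ChirokitError` so callers can catch
one base class at pipeline boundaries.
"""


class ChirokitError(Exception):
    """Base class for all chirokit errors."""


class FormatError(ChirokitError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(ChirokitError):
    """An in-memory object or argument violates a documented invariant."""


class RangeError(ValidationError):
    """A requested window or wavelength lies outside the available grid."""


class DegenerateInputError(ChirokitError):
    """Input is formally valid but carries no usable signal (e.g. zero UV area)."""


class InconsistentReferenceError(ChirokitError):
    """A measured g-factor implies |ee| far above 1: the reference cannot be right."""


class UndefinedCVError(DegenerateInputError):
    """Coefficient of variation is undefined because the mean is (near) zero."""


class IndeterminateAssignmentError(ChirokitError):
    """The simulated spectrum is too weak at the chosen wavelength to call a sign."""
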