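"""Exception hierarchy for the package.

Every contract violation raises a subclass of :class:`KdeknnError` so callers
can catch package errors without masking programming mistakes.
"""

from __future__ import annotations


class KdeknnError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(KdeknnError):
    """Column names, label values or shapes do not match the expected schema."""


class ParseError(KdeknnError):
    """A cell in an input file could not be parsed as a numeric value."""


class DataError(KdeknnError):
    """Input data violates a numeric precondition (non-finite, empty, missing)."""


class FitError(KdeknnError):
    """A model could not be fitted (degenerate support, singular covariance...)."""


class NotFittedError(KdeknnError):
    """A model was used before being fitted."""


class StratificationError(KdeknnError):
    """A class is too small to appear in both sides of a stratified split."""


class ConvergenceError(KdeknnError):
    """The generation loop hit its iteration cap before meeting its targets.

    Carries the partial :class:`~kdeknn.generator.GenerationReport` in
    ``self.report`` so callers can inspect rejection rates and relax the
    privacy threshold or bandwidth.
    """

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report
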