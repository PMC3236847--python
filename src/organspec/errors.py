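"""Exception hierarchy."""


class OrganSpecError(Exception):
    """Base class for all package errors."""


class FormatError(OrganSpecError):
    """A tabular input does not match the expected dialect (e.g. a
    mandatory column is missing); the message names the offending column
    or row."""


class EmptyMatrixError(OrganSpecError):
    """An operation produced or received a count matrix with no genes or
    no organs."""


class VocabularyError(OrganSpecError):
    """A label is outside a closed vocabulary; the message lists the
    valid labels."""


class AmbiguityError(OrganSpecError):
    """The same (gene, organ) cell was supplied more than once where a
    single value is required."""


class CalibrationError(OrganSpecError):
    """Threshold calibration could not satisfy the purity target at any
    candidate (p-value, RZ) pair.  Carries the per-pair comparison table
    in ``table``."""

    def __init__(self, message, table=None):
        super().__init__(message)
        self.table = table


class SanitizationError(OrganSpecError):
    """An identifier contains characters that would corrupt a
    tab-delimited output dialect."""
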