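"""Exception hierarchy.

All felig errors derive from :class:`FeligError` so callers can catch the
package's failures with a single except clause while letting programming
errors propagate.
"""


class FeligError(Exception):
    """Base class for all felig errors."""


class UnitError(FeligError):
    """Dimensionally incompatible or unknown unit conversion."""


class DomainError(FeligError, ValueError):
    """Input outside the mathematical domain of an operation."""


class SchemaError(FeligError):
    """A delimited-text table does not carry the required columns."""


class ParseError(FeligError):
    """A table row could not be parsed; message names row and column."""


class InsufficientDataError(FeligError):
    """Too few usable points remain for a fit."""


class DegenerateFitError(FeligError):
    """Fit abscissa carries no information (e.g. flat titration tail)."""


class FitFailureError(FeligError):
    """A ligand fit failed; carries diagnostics and best-so-far values."""

    def __init__(self, message, diagnostics=None, best=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
        self.best = best
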