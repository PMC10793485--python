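"""Exception hierarchy shared across the package."""


class CrossPrsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CrossPrsError, ValueError):
    """A file or table does not conform to the expected layout."""


class EmptyInputError(CrossPrsError, ValueError):
    """No usable rows/columns remain after filtering."""


class DomainError(CrossPrsError, ValueError):
    """An argument lies outside the mathematically valid region."""


class NumericalError(CrossPrsError, ArithmeticError):
    """A linear-algebra step failed (singular matrix, divergence, ...)."""
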