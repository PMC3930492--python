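"""Exception hierarchy shared across the package."""


class MdfError(Exception):
    """Base class for all package errors."""


class FormulaParseError(MdfError):
    """Malformed reaction formula. Carries the offending position when known."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ConfigurationError(MdfError):
    """Invalid or incomplete model/configuration data (e.g. missing energy)."""


class ConstraintError(MdfError):
    """Inconsistent concentration constraints (lower > upper, fixed+ratio, ...)."""


class SolverError(MdfError):
    """The LP backend failed for a reason other than constraint inconsistency."""
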