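"""Exception hierarchy for kinrace.

All package-specific failures derive from :class:`KinraceError` so callers can
catch one base class; the leaves distinguish bad numeric domains, unit
mismatches, degenerate fits, and malformed input tables.
"""


class KinraceError(Exception):
    """Base class for all kinrace errors."""


class DomainError(KinraceError, ValueError):
    """A numeric argument is outside the mathematically valid domain."""


class UnitError(KinraceError, ValueError):
    """An arithmetic operation would produce or mix incompatible units."""


class UndefinedRaceError(DomainError):
    """Both competing rates of the kinetic race are zero: no outcome defined."""


class InsufficientDataError(KinraceError, ValueError):
    """Too few usable samples/points for the requested fit."""


class ConvergenceError(KinraceError, RuntimeError):
    """An iterative fit failed to converge within its restart budget."""


class ValidationError(KinraceError, ValueError):
    """A record, sequence, or configuration failed structural validation."""
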