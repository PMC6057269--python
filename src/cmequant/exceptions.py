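"""Exception hierarchy shared by all cmequant modules."""


class CMEQuantError(Exception):
    """Base class for all errors raised by cmequant."""


class ConfigurationError(CMEQuantError, ValueError):
    """An imaging/simulation configuration violates its invariants."""


class ParameterError(CMEQuantError, ValueError):
    """A requested distribution or physical parameterization is infeasible."""


class InputError(CMEQuantError, ValueError):
    """Input data violates a precondition (wrong shape, out of bounds, too short)."""


class FitError(CMEQuantError, RuntimeError):
    """A model fit failed to converge or produced an unidentifiable estimate."""


class UndefinedResultError(CMEQuantError, ArithmeticError):
    """The requested summary is undefined for this input (e.g. empty set, zero denominator)."""
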