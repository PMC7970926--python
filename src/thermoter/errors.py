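"""Exception hierarchy."""


class ThermoterError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ThermoterError, ValueError):
    """A physical precondition on an input was violated (negative time,
    non-finite temperature, negative TER, ...)."""


class NumericsError(ThermoterError, ArithmeticError):
    """A numerical routine failed: overflow in an exponential, quadrature
    non-convergence, ill-conditioned inversion."""


class FitError(ThermoterError, RuntimeError):
    """A fitting procedure could not produce estimates (degenerate data,
    non-convergence, identifiability violation)."""


class FormatError(ThermoterError, ValueError):
    """A tabular input file did not match its expected dialect."""
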