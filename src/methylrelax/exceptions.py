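"""Exception hierarchy for methylrelax."""


class MethylRelaxError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MethylRelaxError, ValueError):
    """A physical parameter is outside its valid domain."""


class DegenerateSystemError(MethylRelaxError):
    """The rate matrix has (near-)degenerate eigenvalues; amplitudes of the
    multi-exponential solution are not well defined."""


class FitFailureError(MethylRelaxError):
    """A nonlinear fit failed to converge; the message carries diagnostics."""


class ResolutionError(MethylRelaxError):
    """A numerical propagation step is too coarse for the requested rates."""


class BracketError(MethylRelaxError):
    """A 1-D search could not bracket a minimum inside the allowed range."""


class ParseError(MethylRelaxError, ValueError):
    """A data table or config file violates the expected layout."""
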