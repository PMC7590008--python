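"""Exception hierarchy for the itcdissolve package."""


class ItcDissolveError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ItcDissolveError, ValueError):
    """A value violates a documented precondition or type invariant."""


class DomainError(ItcDissolveError, ValueError):
    """A value is outside the mathematical domain of an expression."""


class TraceParseError(ItcDissolveError, ValueError):
    """A trace file could not be parsed; the message names the offending line."""


class ConfigurationError(ItcDissolveError, ValueError):
    """A configuration is internally inconsistent or physically unusable."""


class BaselineError(ItcDissolveError, RuntimeError):
    """Baseline correction has no support (e.g. peaks cover the whole trace)."""


class CalibrationError(ItcDissolveError, RuntimeError):
    """Dilution-shape calibration failed (e.g. no resolvable peak)."""


class FitError(ItcDissolveError, RuntimeError):
    """A least-squares fit could not be carried out."""
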