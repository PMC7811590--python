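"""Exception hierarchy shared across the package."""


class PulmoUQError(Exception):
    """Base class for all package errors."""


class NetworkParseError(PulmoUQError, ValueError):
    """A network file could not be parsed; message names the offending record."""


class NetworkValidationError(PulmoUQError, ValueError):
    """A vessel network violates a topological or geometric invariant."""


class ConfigurationError(PulmoUQError, ValueError):
    """Inconsistent or physically impossible configuration values."""


class DomainError(PulmoUQError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ContractError(PulmoUQError, ValueError):
    """Caller violated an interface contract (shape/length/name mismatch)."""


class SolverError(PulmoUQError, RuntimeError):
    """The PDE solver failed (Newton non-convergence, CFL violation, blow-up)."""


class NumericalError(PulmoUQError, RuntimeError):
    """A numerical routine failed (e.g. Cholesky factorization)."""


class DiagnosticError(PulmoUQError, RuntimeError):
    """A convergence diagnostic could not be computed (degenerate input)."""
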