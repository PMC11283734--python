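"""Exception hierarchy shared across the simulator."""


class LiversimError(Exception):
    """Base class for all package errors."""


class ParameterError(LiversimError, ValueError):
    """A distribution or scenario parameter is outside its valid range."""


class DomainError(LiversimError, ValueError):
    """A function argument (e.g. a probability) is outside its domain."""


class InputError(LiversimError, ValueError):
    """Malformed user input: tables, mixes, empty data."""


class FitError(LiversimError, RuntimeError):
    """Maximum-likelihood fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CalibrationError(LiversimError, RuntimeError):
    """A calibration target is unattainable under the requested family."""


class ConfigurationError(LiversimError, KeyError):
    """A required registry stratum or config entry is missing."""


class LogicError(LiversimError, RuntimeError):
    """Internal contract violation (e.g. transplanting a patient not listed)."""


class SimulationStallError(LiversimError, RuntimeError):
    """The event calendar ran dry (or exceeded its horizon) with tracked
    patients still waiting."""


class ComparisonError(LiversimError, ValueError):
    """Strategies compared under incompatible configurations."""
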