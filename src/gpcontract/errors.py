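"""Exception hierarchy for gpcontract."""


class GPContractError(Exception):
    """Base class for all package errors."""


class ParameterError(GPContractError, ValueError):
    """A parameter or lookup table failed validation."""


class DomainError(GPContractError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class SimulationError(GPContractError, RuntimeError):
    """The integrator produced a non-finite value.

    Carries the simulation time at which the problem was detected.
    """

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class ConfigError(GPContractError, ValueError):
    """A configuration file failed to parse or validate."""
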