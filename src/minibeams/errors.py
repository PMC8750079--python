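"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument is outside the physical domain of an operation."""


class ConfigError(ValueError):
    """A scenario / run configuration is invalid or incomplete."""


class InfeasibleFieldError(RuntimeError):
    """The requested deflection cannot be achieved with a feasible field.

    Attributes
    ----------
    achievable : tuple[float, float] | None
        Landing-position interval (mm) reachable within the solver bracket,
        when known.
    """

    def __init__(self, message, achievable=None):
        super().__init__(message)
        self.achievable = achievable


class OutOfBoundsError(RuntimeError):
    """A trajectory left the phantom laterally.

    The partially integrated trajectory is attached as ``trajectory``.
    """

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory
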