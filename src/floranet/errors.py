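"""Exception types shared across the package."""


class FloranetError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FloranetError, ValueError):
    """An argument lies outside the mathematically admissible domain."""


class ModeError(FloranetError, ValueError):
    """An operation requiring constant inputs received time-varying ones."""


class DivergenceError(FloranetError, RuntimeError):
    """A trajectory became non-finite or left the admissible range."""

    def __init__(self, time_min: float, message: str | None = None):
        self.time_min = time_min
        super().__init__(message or f"trajectory diverged at t = {time_min:g} min")


class BoundViolationError(FloranetError, ValueError):
    """A steady-state value violates the existence bound x2 < beta4*F1/d2."""


class BracketError(FloranetError, RuntimeError):
    """A root search found no sign change in the requested bracket."""


class ConfigurationError(FloranetError, ValueError):
    """An invalid run or generator configuration."""
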