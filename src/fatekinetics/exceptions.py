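"""Exception types shared across the package."""


class FateKineticsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FateKineticsError, ValueError):
    """A domain object or argument violates its invariants."""


class ConditionLookupError(FateKineticsError, KeyError):
    """A culture-condition name is not present in the registry."""

    def __init__(self, name: str, known: tuple[str, ...]):
        self.name = name
        self.known = known
        super().__init__(
            f"unknown culture condition {name!r}; registered conditions: "
            f"{', '.join(sorted(known))}"
        )

    def __str__(self) -> str:  # KeyError would repr() the message otherwise
        return self.args[0]


class IdentifiabilityError(FateKineticsError, ValueError):
    """The dataset cannot constrain the requested parameters."""


class FitConvergenceError(FateKineticsError, RuntimeError):
    """No optimizer start converged."""


class IntegrationError(FateKineticsError, RuntimeError):
    """The numerical integrator failed."""


class ConfigError(FateKineticsError, ValueError):
    """A run configuration violates its schema."""
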