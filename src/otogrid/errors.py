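"""Exception hierarchy shared across the package."""


class OtogridError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OtogridError, ValueError):
    """A run configuration or parameter set violates an invariant."""


class InvalidInputError(OtogridError, ValueError):
    """An operation received non-finite or malformed numerical input."""


class IntegrationError(OtogridError, RuntimeError):
    """The integrator produced a non-finite or out-of-bounds state.

    Carries the step index and the flat cell index of the first offending
    bundle so unit mistakes surface with context.
    """

    def __init__(self, message: str, step: int | None = None, cell: int | None = None):
        super().__init__(message)
        self.step = step
        self.cell = cell
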