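"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid argument values (unknown driver name, mismatched series, ...)."""


class ConfigurationError(ValueError):
    """Invalid configuration (unknown deposition profile, unusable table row, ...)."""


class ConvergenceError(RuntimeError):
    """Spin-up failed to reach equilibrium within the iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class NumericalError(RuntimeError):
    """Non-finite state encountered during integration."""
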