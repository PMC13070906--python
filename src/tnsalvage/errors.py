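"""Exception types shared across the package."""


class TnsalvageError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TnsalvageError, ValueError):
    """A configuration object violates its invariants.

    The message always names the offending field.
    """


class CalibrationError(TnsalvageError, RuntimeError):
    """A calibration target is infeasible or the solver failed."""


class ConvergenceError(TnsalvageError, RuntimeError):
    """An iterative fit did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class BundleError(TnsalvageError, RuntimeError):
    """A result bundle is missing, malformed, or fails its checksums."""


class DegenerateModelWarning(UserWarning):
    """The requested model has more classes than distinct data patterns."""
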