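"""Exception types shared across the package."""


class RDHealthError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RDHealthError, ValueError):
    """Invalid configuration; the message names the offending field."""


class ConvergenceError(RDHealthError, RuntimeError):
    """Optimizer failed to reach the required gradient tolerance.

    Carries the per-iteration gradient-norm trace in ``trace``.
    """

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class SeparationError(RDHealthError, RuntimeError):
    """(Quasi-)perfect separation: a coefficient diverged during fitting."""


class PipelineError(RDHealthError, RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
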