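"""Exception hierarchy used across the package."""


class ToxnetError(Exception):
    """Base class for package-specific failures."""


class ParseError(ToxnetError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if path is not None and line is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


class ValidationError(ToxnetError, ValueError):
    """Input violated a documented invariant (confidence bounds, self-loops, ...)."""


class ConvergenceError(ToxnetError, RuntimeError):
    """An iterative solver failed to reach its tolerance; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
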