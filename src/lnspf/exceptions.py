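"""Exception types raised across the package."""


class ParseError(ValueError):
    """An input table could not be parsed.

    Carries the offending path and 1-based line number where available.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)


class ConvergenceError(RuntimeError):
    """An iterative score propagation failed to converge."""

    def __init__(self, message: str, residual: float | None = None,
                 spectral_radius: float | None = None):
        self.residual = residual
        self.spectral_radius = spectral_radius
        super().__init__(message)
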