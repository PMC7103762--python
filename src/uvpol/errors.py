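"""Exception hierarchy for uvpol."""


class UvpolError(Exception):
    """Base class for all uvpol errors."""


class ConfigError(UvpolError):
    """A parameter or configuration value violates an invariant.

    ``field`` names the offending SimParams/GeneSpec field when known.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message if field is None else f"{field}: {message}")
        self.field = field


class StateError(UvpolError):
    """An operation was applied to a simulation state that cannot accept it
    (e.g. introducing damage twice)."""


class ConvergenceError(UvpolError):
    """Burn-in failed to reach initiation/completion flux balance within the
    hard time cap."""


class CalibrationError(UvpolError):
    """The degradation-hazard calibration target is unreachable within the
    bisection bracket.  ``bracket`` carries (hazard_lo, hazard_hi) and the
    half-lives achieved at the bracket ends."""

    def __init__(self, message: str, bracket=None):
        super().__init__(message)
        self.bracket = bracket


class BedgraphParseError(UvpolError):
    """A bedGraph file could not be parsed; ``line_no`` is 1-based."""

    def __init__(self, message: str, line_no: int | None = None):
        super().__init__(message if line_no is None else f"line {line_no}: {message}")
        self.line_no = line_no
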