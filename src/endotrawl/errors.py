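"""Exception hierarchy shared by all pipeline stages."""


class EndotrawlError(Exception):
    """Base class for all package-specific errors."""


class InputError(EndotrawlError):
    """Invalid input data (wrong alphabet, out-of-bounds interval, ...)."""


class ParameterError(EndotrawlError):
    """A parameter is outside its documented range."""


class SizingError(EndotrawlError):
    """Requested construction does not fit (genome too short, infeasible fragmentation)."""


class ConfigurationError(EndotrawlError):
    """Missing or inconsistent configuration (absent marker, missing reference gene)."""


class ComputationError(EndotrawlError):
    """A computation cannot proceed (degenerate self-score, ...)."""


class AuditError(EndotrawlError):
    """Synteny audit cannot run (empty gene set)."""


class ParseError(EndotrawlError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
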