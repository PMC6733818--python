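"""Exception types shared across the toolkit."""


class SatconnectError(Exception):
    """Base class for all toolkit errors."""


class ParseError(SatconnectError):
    """A sequence file could not be parsed; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class FormatError(SatconnectError):
    """A record violates format constraints (e.g. seq/qual length mismatch)."""


class PairingError(SatconnectError):
    """Forward/reverse mate files disagree; carries the offending rank."""

    def __init__(self, message: str, rank: int | None = None):
        self.rank = rank
        if rank is not None:
            message = f"{message} (pair rank {rank})"
        super().__init__(message)


class PipelineError(SatconnectError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, message: str, stage: str | None = None):
        self.stage = stage
        if stage is not None:
            message = f"[{stage}] {message}"
        super().__init__(message)
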