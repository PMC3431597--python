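"""Exception hierarchy."""


class SplitRaceError(Exception):
    """Base class for package errors."""


class ParameterError(SplitRaceError, ValueError):
    """A parameter violates its documented range or invariant."""


class ConfigurationError(SplitRaceError, ValueError):
    """Inconsistent or incomplete configuration (e.g. a gene without variant
    sites, or a missing config key)."""


class FastaParseError(SplitRaceError, ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class PipelineError(SplitRaceError, RuntimeError):
    """A pipeline stage failed; message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
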