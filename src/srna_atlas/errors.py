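"""Exception hierarchy.

All package errors derive from :class:`SrnaAtlasError` so callers can catch
one type; the CLI maps subclasses onto distinct exit codes (usage, data,
internal).
"""


class SrnaAtlasError(Exception):
    """Base class for all errors raised by srna-atlas."""


class FormatError(SrnaAtlasError):
    """A malformed input file.

    Carries the offending line number when one is known.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix = f"{path}:"
            if line is not None:
                prefix += f"{line}:"
            prefix += " "
        elif line is not None:
            prefix = f"line {line}: "
        super().__init__(prefix + message)


class PlacementError(SrnaAtlasError):
    """Synthetic genome construction could not place a feature."""


class DataError(SrnaAtlasError):
    """Inputs are well-formed but violate a precondition."""


class PipelineError(SrnaAtlasError):
    """A pipeline stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
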