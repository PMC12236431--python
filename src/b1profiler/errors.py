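"""Exception hierarchy for the profiler.

All errors raised deliberately by this package derive from :class:`ProfilerError`
so callers (and the CLI) can distinguish usage problems from genuine bugs.
"""


class ProfilerError(Exception):
    """Base class for all errors raised by b1profiler."""


class ParseError(ProfilerError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ConfigurationError(ProfilerError):
    """Invalid thresholds, options, or run configuration."""


class ConsistencyError(ProfilerError):
    """Cross-table inconsistency (unknown genome, unknown gene symbol, ...)."""
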