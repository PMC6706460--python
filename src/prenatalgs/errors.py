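"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A simulation or caller parameter is out of its valid range."""


class CoordinateError(ValueError):
    """A genomic interval falls outside the coordinate frame in use."""


class InputError(ValueError):
    """An input table is empty, malformed or inconsistent."""


class RecordError(InputError):
    """A single record failed to parse; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message} (line {line})" if line is not None else message)


class CandidateRejected(ValueError):
    """A candidate CNV region could not be refined into a call."""
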