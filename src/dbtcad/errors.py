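"""Exception hierarchy for the CADe pipeline.

Exit-code mapping used by the CLI: validation errors -> 2, I/O and format
errors -> 3, stage failures inside the pipeline -> 4.
"""


class DbtCadError(Exception):
    """Base class for all package errors."""


class ValidationError(DbtCadError, ValueError):
    """Invalid parameter or input contract violation."""


class FormatError(DbtCadError, IOError):
    """File exists but is not a supported/consistent volumetric format."""


class ParseError(DbtCadError, ValueError):
    """Malformed row or field in a tabular annotation file."""


class NoValidThresholdError(DbtCadError, ValueError):
    """A count-targeted threshold search found no usable threshold
    (e.g. the field is constant)."""


class GenerationError(DbtCadError, RuntimeError):
    """Phantom synthesis failed (e.g. cluster placement retries exhausted)."""


class StageError(DbtCadError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
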