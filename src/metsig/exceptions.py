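"""Exception hierarchy for the pipeline.

Every error raised by the package derives from :class:`MetsigError` so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class MetsigError(Exception):
    """Base class for all package errors."""


class ConfigError(MetsigError):
    """An invalid configuration field; the message names the field."""


class FormatError(MetsigError):
    """A malformed input file; the message locates the offending content."""


class StageError(MetsigError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
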