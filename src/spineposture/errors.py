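"""Exception hierarchy shared by the library and the CLI."""


class SpinePostureError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SpinePostureError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(SpinePostureError):
    """A file could not be parsed; the message names file and line."""


class PipelineError(SpinePostureError):
    """A posture-estimation stage failed on otherwise well-formed input."""
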