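"""Exception hierarchy shared across the package."""


class TTSeqKitError(Exception):
    """Base class for all errors raised by ttseqkit."""


class FormatError(TTSeqKitError, ValueError):
    """A file could not be parsed (malformed line, bad coordinates, ...)."""


class DataError(TTSeqKitError, ValueError):
    """An in-memory object violates an invariant or an operation precondition."""


class PipelineError(TTSeqKitError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
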