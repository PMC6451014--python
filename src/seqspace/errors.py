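"""Exception hierarchy shared by all modules."""


class SeqSpaceError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(SeqSpaceError, ValueError):
    """Invalid data: bad alphabet, ragged alignment, duplicate taxa, ..."""


class FormatError(SeqSpaceError, ValueError):
    """A file does not parse under the declared dialect."""


class ConvergenceError(SeqSpaceError, RuntimeError):
    """An iterative numerical routine failed to converge."""
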