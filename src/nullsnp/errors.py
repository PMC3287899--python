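"""Exception hierarchy. Each class carries the CLI exit code for its failure family."""


class NullSnpError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(NullSnpError, ValueError):
    """Invalid user input: bad options, misaligned tables, impossible parameters."""

    exit_code = 2


class DataFormatError(NullSnpError):
    """Unreadable or malformed input file."""

    exit_code = 3


class ComputationError(NullSnpError):
    """A statistical computation cannot proceed (degenerate design, empty null set...)."""

    exit_code = 4
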