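"""Exception hierarchy shared across the package."""


class HlaQcError(Exception):
    """Base class for all package errors."""


class FormatError(HlaQcError):
    """Malformed input content (FASTA/FASTQ/TSV)."""


class ArgumentError(HlaQcError):
    """Invalid user-supplied parameter."""


class InputError(HlaQcError):
    """Missing or unreadable input file/folder."""
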