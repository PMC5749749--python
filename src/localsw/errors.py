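"""Exception hierarchy shared across the package."""


class LocalSWError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(LocalSWError):
    """A parameter, flag or config-file value is out of range or inconsistent."""


class InputError(LocalSWError):
    """An input sequence or record violates a precondition."""


class FormatError(LocalSWError):
    """A file could not be parsed (matrix, FASTA/FASTQ, config)."""
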