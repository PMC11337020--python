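"""Exception hierarchy shared across the pipeline."""


class MfcloneError(Exception):
    """Base class for all package errors."""


class FormatError(MfcloneError):
    """An on-disk input violates the expected file format."""


class ContractError(MfcloneError):
    """Inputs to an operation violate its preconditions."""


class ConfigurationError(MfcloneError):
    """A parameter or gene-list configuration cannot be applied to the data."""


class NoReferenceCellsError(MfcloneError):
    """Differential expression requested against an empty reference group."""


class NoTCRInformationError(MfcloneError):
    """A sample carries no usable TCR contigs, so no clone can be called."""
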