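"""Exception hierarchy shared across the pipeline."""


class BetrewireError(Exception):
    """Base class for all package errors."""


class FormatError(BetrewireError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(BetrewireError):
    """A file parsed but carries invalid values (negative counts, bad letters...)."""


class ContractError(BetrewireError):
    """A function was called with arguments violating its preconditions."""


class ConfigurationError(BetrewireError):
    """A run configuration is inconsistent (missing time point, empty map...)."""
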