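"""Exception types shared across the pipeline."""


class CirrdxError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(CirrdxError):
    """Invalid parameter or configuration value; message names the field."""


class DomainError(CirrdxError):
    """Input outside the mathematical domain of an operation."""


class DegenerateInputError(CirrdxError):
    """Structurally valid input on which the operation is undefined
    (e.g. an all-constant volume, a single-class label vector)."""
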