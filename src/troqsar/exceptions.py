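"""Exception hierarchy for troqsar."""


class TroqsarError(Exception):
    """Base class for all troqsar errors."""


class InvalidInputError(TroqsarError, ValueError):
    """An input value is non-finite, out of domain, or malformed."""


class InsufficientDataError(TroqsarError, ValueError):
    """Too few records to perform the requested fit."""


class DegenerateDesignError(TroqsarError, ValueError):
    """The regression design is degenerate (e.g. constant descriptor)."""


class SchemaError(TroqsarError, ValueError):
    """A tabular input does not satisfy the compound-table schema."""


class NotFittedError(TroqsarError, RuntimeError):
    """A model was used before (or without) a successful fit."""
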