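"""Exception hierarchy for craniomorph."""


class CraniomorphError(Exception):
    """Base class for all craniomorph errors."""


class SchemaError(CraniomorphError):
    """A required column is missing or mis-mapped in an input table."""


class ValidationError(CraniomorphError):
    """A record violates the craniometric data invariants."""


class FitError(CraniomorphError):
    """A model cannot be fitted on the given data (degenerate input)."""
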