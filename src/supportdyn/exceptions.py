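"""Exception hierarchy for supportdyn."""


class SupportDynError(Exception):
    """Base class for all supportdyn errors."""


class SchemaError(SupportDynError):
    """Input rows/columns do not match the expected schema."""


class IntegrityError(SupportDynError):
    """Duplicate identifiers or inconsistent cross-references."""


class ValidationError(SupportDynError):
    """A value violates a domain invariant (e.g. a Likert score outside 1-7)."""


class DomainError(SupportDynError):
    """An operation was called on input outside its mathematical domain."""


class ConfigError(SupportDynError):
    """Invalid configuration (missing lexicon, bad proportions, bad matrix)."""


class FitError(SupportDynError):
    """A model could not be fitted (degenerate data, non-convergence)."""
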