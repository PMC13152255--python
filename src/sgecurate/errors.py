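"""Exception hierarchy for the curation pipeline.

All package errors derive from :class:`CurationError`, itself a
``ValueError``, so callers can catch one type at the pipeline boundary.
"""


class CurationError(ValueError):
    """Base class for all errors raised by this package."""


class EvidenceParseError(CurationError):
    """An ACMG/AMP evidence token could not be parsed."""


class ValidationError(CurationError):
    """Input values violate a documented precondition."""


class SchemaError(CurationError):
    """A variant table is missing a required column or is malformed."""


class ConfigError(CurationError):
    """A configuration file or cohort specification is invalid."""
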