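"""Exception hierarchy."""


class ParencliticError(Exception):
    """Base class for all package errors."""


class SchemaError(ParencliticError):
    """A required column is absent or the file layout is wrong."""


class CohortParseError(ParencliticError):
    """A cell could not be parsed as the expected type."""


class CohortValidationError(ParencliticError):
    """The cohort table violates an invariant (duplicate ids, bad codes...)."""


class ConfigError(ParencliticError):
    """A configuration value violates its constraints."""


class DegenerateFitError(ParencliticError):
    """A regression cannot be fitted (e.g. constant predictor)."""


class NoReferenceClassError(ParencliticError):
    """No survivors are available to build the reference model."""


class NoEventsError(ParencliticError):
    """A survival computation was requested with zero observed events."""
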