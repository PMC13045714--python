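"""Exception hierarchy."""


class FairfedError(Exception):
    """Base class for all package errors."""


class SchemaError(FairfedError):
    """Tabular source or column metadata violates a structural requirement."""


class MappingError(FairfedError):
    """A semantic mapping refers to unknown schema classes or vocabulary terms."""


class QueryError(FairfedError):
    """A consortium query is malformed or cannot be compiled."""


class FederationError(FairfedError):
    """Hub-level orchestration failure (unknown task, empty node set, ...)."""


class FitError(FairfedError):
    """Model fitting cannot proceed (no events, singular information, ...)."""


class ProfileError(FairfedError):
    """A fixture profile is internally inconsistent or was not reproduced."""
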