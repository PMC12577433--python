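"""Exception hierarchy shared across the package."""


class TextoraError(Exception):
    """Base class for all package errors."""


class FormatError(TextoraError):
    """An input file violates its expected schema."""


class ParameterError(TextoraError, ValueError):
    """An argument is outside its valid range or inconsistent with the data."""


class ContractError(TextoraError):
    """A pluggable component (e.g. an embedder) violated its contract."""


class FitError(TextoraError):
    """Model fitting failed, e.g. the vocabulary is empty after filtering."""


class QueryError(TextoraError):
    """A query cannot be run against the model (e.g. no known genes)."""


class LookupError_(TextoraError, KeyError):
    """An entity or term is unknown to the model."""
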