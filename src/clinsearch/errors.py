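"""Exception hierarchy shared by all clinsearch modules."""


class ClinSearchError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ClinSearchError):
    """A file does not parse under its declared dialect (message names the record/line)."""


class IntegrityError(ClinSearchError):
    """A referential invariant is violated (dangling reference, missing endpoint)."""


class ConceptLookupError(ClinSearchError, KeyError):
    """A concept id does not resolve in the loaded terminologies."""


class ConfigurationError(ClinSearchError):
    """Invalid configuration value (unknown language tag, unknown output format...)."""


class SchemaError(ClinSearchError):
    """Entity type / attribute / relationship not declared, or declared inconsistently."""


class EntityValidationError(ClinSearchError):
    """An entity's attribute value does not conform to its schema kind."""


class ConflictError(ClinSearchError):
    """Duplicate key on insert."""


class QueryError(ClinSearchError):
    """Semantically invalid query (incompatible predicate, missing projection path...)."""


class ParseError(ClinSearchError):
    """Query text does not parse; carries position information."""

    def __init__(self, message: str, pos: int, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.pos = pos
        self.line = line
        self.column = column


class GenerationError(ClinSearchError):
    """Synthetic-data parameters are contradictory or a template slot cannot be filled."""


class DegenerateInputError(ClinSearchError):
    """A statistical routine received an input with no usable information."""
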