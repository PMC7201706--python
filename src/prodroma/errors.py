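"""Exception hierarchy for record validation and analysis errors."""


class ProdromaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ProdromaError):
    """A required column is missing or a header does not match."""


class DateParseError(ProdromaError):
    """A date field could not be parsed as ISO-8601; names the offending rows."""


class VocabularyError(ProdromaError):
    """An event category is outside the closed controlled vocabulary."""


class ReferentialError(ProdromaError):
    """An event references a patient_id absent from the patient table."""


class ConfigError(ProdromaError):
    """An invalid simulation, roster or window configuration."""


class EstimationError(ProdromaError):
    """The conditional-likelihood fit failed for a reason other than separation."""


class AssemblyError(ProdromaError):
    """A reporting series could not be assembled (missing horizon or feature)."""
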