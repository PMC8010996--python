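"""Exception types shared across the package."""


class RecqtlError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(RecqtlError):
    """A simulation or analysis configuration violates its constraints."""


class PhaseError(RecqtlError):
    """A VCF genotype is not phased; the record is named in the message."""


class MissingGenotypeError(RecqtlError):
    """A genotype call is missing; phased panels must be complete."""


class SchemaError(RecqtlError):
    """A tabular input does not match the expected column schema."""


class ParseError(RecqtlError):
    """A cell could not be parsed; the offending line is named."""


class SingularDesignError(RecqtlError):
    """A fixed-effect design matrix is rank deficient; aliased columns are named."""


class IdMismatchError(RecqtlError):
    """Individual identifiers of two inputs do not align."""
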