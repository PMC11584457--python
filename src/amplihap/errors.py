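"""Exception hierarchy for input validation and pipeline failures."""


class AmpliHapError(Exception):
    """Base class for all package errors."""


class ValidationError(AmpliHapError, ValueError):
    """An input table or parameter violates a documented invariant."""


class MissingColumnError(ValidationError):
    """A required column is absent from an input table."""


class EmptyTableError(ValidationError):
    """An input table has no rows."""


class DuplicateKeyError(ValidationError):
    """A key column (or key tuple) contains duplicates."""


class BarcodeError(ValidationError):
    """A barcode is not valid DNA or barcode lengths are ragged."""


class CoordinateError(ValidationError):
    """Marker genomic coordinates are inconsistent with the reference sequence."""


class ConfigError(ValidationError):
    """Unknown configuration key or out-of-range parameter value."""


class DesyncError(AmpliHapError):
    """Paired FASTQ files are out of sync (unequal counts or mismatched ids)."""


class PipelineError(AmpliHapError):
    """A pipeline stage failed; message carries the stage name."""


class EmptyResultError(PipelineError):
    """A filtering stage removed every row; message attributes the stage."""
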