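"""Exception hierarchy for crisprtile.

Validation/schema errors map to CLI exit code 2, runtime errors to 1.
"""


class CrisprTileError(Exception):
    """Base class for all crisprtile errors."""


class ValidationError(CrisprTileError, ValueError):
    """An argument or input value violates a documented precondition."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns or carries unknown keys."""


class GenerationError(CrisprTileError, RuntimeError):
    """The simulator could not satisfy a construction constraint (e.g. unique
    spacer keys) within its bounded retry budget."""


class EmptyBinError(CrisprTileError, RuntimeError):
    """A sorting bin received no cells, so sequencing probabilities are undefined."""


class DegenerateSampleError(CrisprTileError, RuntimeError):
    """A sample has zero sequencing depth; normalization is undefined."""


class FastqParseError(CrisprTileError, RuntimeError):
    """A FASTQ stream is malformed; the message names the offending record."""


class UndefinedCorrelationError(CrisprTileError, RuntimeError):
    """Correlation requested for a zero-variance vector."""
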