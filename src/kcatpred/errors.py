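"""Exception hierarchy.

Every error raised by this package derives from :class:`KcatPredError` so
callers can catch the package's failures with a single except clause while
still discriminating schema problems from chemistry problems.
"""


class KcatPredError(Exception):
    """Base class for all package errors."""


class SchemaError(KcatPredError):
    """A table is missing required columns or has malformed structure."""


class IntegrityError(KcatPredError):
    """Duplicate identifiers or an on-disk container missing declared data."""


class RowError(KcatPredError):
    """A single data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class FormatError(KcatPredError):
    """A sequence file violates its format (e.g. FASTA body before header)."""


class ReactionParseError(KcatPredError):
    """A reaction SMILES lacks the substrate>agent>product separator structure."""


class ChemistryError(KcatPredError):
    """A molecule SMILES failed to parse under the cheminformatics backend."""


class ParameterError(KcatPredError):
    """An argument is outside its documented domain."""


class ShapeError(KcatPredError):
    """Array dimensions do not line up."""


class DataError(KcatPredError):
    """Non-finite or otherwise unusable numeric data."""


class AlphabetError(KcatPredError):
    """A sequence contains characters outside the amino-acid alphabet."""


class SelectionError(KcatPredError):
    """A requested feature block does not exist or is misaligned."""


class ArchitectureError(KcatPredError):
    """A network configuration is impossible for the given input shape."""


class NamingError(KcatPredError):
    """Duplicate or empty names where unique labels are required."""


class StageError(KcatPredError):
    """A pipeline stage failed; names the stage and wraps the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
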