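"""Exception hierarchy shared across the package."""


class DicistroError(Exception):
    """Base class for all errors raised by this package."""


class FastaFormatError(DicistroError):
    """Malformed FASTA input (bad header, stray text, illegal residue)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class EmptyInputError(DicistroError):
    """An input file or sequence set contained no usable records."""


class DuplicateIdError(DicistroError):
    """Two records in one loaded set share an identifier."""


class AlphabetError(DicistroError):
    """A sequence contains a character outside {A,C,G,T,U,N}."""

    def __init__(self, character: str, offset: int):
        self.character = character
        self.offset = offset
        super().__init__(
            f"illegal character {character!r} at offset {offset} "
            "(expected A/C/G/T/U/N, case-insensitive)"
        )


class CoordinateError(DicistroError):
    """A feature coordinate falls outside the sequence it annotates."""


class NotDicistronicError(DicistroError):
    """Fewer than two qualifying non-overlapping forward ORFs were found."""


class AmbiguousArchitectureError(DicistroError):
    """Top ORF candidates tie in a way the selection rule cannot resolve."""

    def __init__(self, message: str, candidates=None):
        self.candidates = candidates or []
        super().__init__(message)


class TranslationError(DicistroError):
    """An ORF span is inconsistent (e.g. internal in-frame stop codon)."""


class PatternError(DicistroError):
    """A motif pattern string cannot be parsed."""


class CleavageSchemeError(DicistroError):
    """Cleavage cut positions are not strictly increasing or out of range."""


class InsufficientSequenceError(DicistroError):
    """Too little informative (non-N) sequence for composition analysis."""


class UndefinedRatioError(DicistroError):
    """An observed/expected dinucleotide ratio is undefined (zero expectation)."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(
            "undefined observed/expected ratio for dinucleotide(s): "
            + ", ".join(self.pairs)
        )


class LabelError(DicistroError):
    """Host labels are inconsistent with the sequence set or model."""


class DataError(DicistroError):
    """Non-finite or otherwise unusable numeric data."""


class DimensionError(DicistroError):
    """Feature vector length does not match the fitted model."""


class InfeasibleSpecError(DicistroError):
    """A synthetic-data specification cannot be realized."""


class RetryLimitError(DicistroError):
    """Rejection sampling exhausted its retry budget."""


class StageError(DicistroError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
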