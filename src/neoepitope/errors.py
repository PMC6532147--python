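"""Exception types shared across the package."""


class NeoepitopeError(Exception):
    """Base class for all package errors."""


class FormatError(NeoepitopeError):
    """An input file violates its declared format."""


class HlaParseError(FormatError):
    """An HLA allele token could not be normalized."""


class AnnotationError(NeoepitopeError):
    """A transcript/genome inconsistency prevents annotation."""


class ReferenceMismatchError(AnnotationError):
    """The projected REF allele does not match the transcript sequence."""

    def __init__(self, expected: str, found: str, offset: int):
        self.expected = expected
        self.found = found
        self.offset = offset
        super().__init__(
            f"REF mismatch at CDS offset {offset}: variant says {expected!r}, "
            f"transcript has {found!r}"
        )


class EmptyTailError(AnnotationError):
    """A frameshift/stop-loss produced no novel residues before the new stop."""


class PredictionError(NeoepitopeError):
    """A predictor cannot score a (peptide, allele) pair."""


class ConfigError(NeoepitopeError):
    """Invalid pipeline configuration."""
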