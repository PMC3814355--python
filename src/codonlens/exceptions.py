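"""Exception hierarchy shared across the package."""


class CodonAnalysisError(Exception):
    """Base class for all errors raised by codonlens."""


class FrameError(CodonAnalysisError):
    """CDS length is not divisible by three."""

    def __init__(self, gene_id: str, length: int):
        self.gene_id = gene_id
        self.length = length
        super().__init__(f"CDS of gene {gene_id!r} has length {length}, not divisible by 3")


class EmptyInputError(CodonAnalysisError):
    """A statistic was requested on empty counts or an empty collection."""


class DomainError(CodonAnalysisError, ValueError):
    """An argument is outside its mathematical domain."""


class MissingFamilyError(CodonAnalysisError):
    """A synonymous family required by the operation has no data."""

    def __init__(self, families):
        self.families = sorted(families)
        super().__init__(f"no data for synonymous families: {', '.join(self.families)}")


class AlignmentError(CodonAnalysisError):
    """A per-nucleotide profile does not align with its CDS."""


class EmptyJoinError(CodonAnalysisError):
    """Joining gene records with a property table produced no rows."""


class DegenerateNullError(CodonAnalysisError):
    """A null distribution has zero spread; a Z-score is undefined."""


class InsufficientDataError(CodonAnalysisError):
    """Too few paired observations for a correlation."""


class CorrelationUndefinedError(CodonAnalysisError):
    """One of the variables is constant; a correlation is undefined."""


class MissingScoreError(CodonAnalysisError):
    """A codon present in a gene has no score in the lookup table."""

    def __init__(self, codons):
        self.codons = sorted(codons)
        super().__init__(f"no score available for codons: {', '.join(self.codons)}")


class SchemaError(CodonAnalysisError):
    """A tabular input file does not match the expected schema."""


class DuplicateIdError(SchemaError):
    """A FASTA file contains the same record id twice."""


class DegenerateRangeError(CodonAnalysisError):
    """All values are identical; equal-width binning is impossible."""
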