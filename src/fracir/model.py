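"""Core genomic data model.

All coordinates inside the package are 0-based, half-open (BED convention).
GTF input (1-based, closed) is converted on read; BED passes through
unchanged.  An :class:`IntronRecord` is the unit of every downstream
analysis: retention quantification, differential testing, taxonomy,
cis-feature and crosslink-enrichment scoring are all keyed on its
``intron_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Reference sequence name (must be non-empty).
    start, end : int
        0-based start (inclusive) and end (exclusive); ``start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True if the 0-based position lies inside the interval."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene with one exon chain per transcript.

    Exons are stored as ``(start, end)`` tuples sorted by genomic start
    regardless of strand; all exons of a gene share ``chrom`` and
    ``strand``.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def validate(self) -> None:
        for tx_id, exons in self.transcripts.items():
            prev_end = -1
            for start, end in exons:
                if start >= end:
                    raise ValueError(
                        f"{self.gene_id}/{tx_id}: empty exon [{start},{end})"
                    )
                if start < prev_end:
                    raise ValueError(
                        f"{self.gene_id}/{tx_id}: exons overlap or are unsorted"
                    )
                prev_end = end


@dataclass(frozen=True)
class IntronRecord:
    """A genomic intron attributed to its host gene.

    ``ordinal`` is the 1-based position of the intron among the host
    gene's introns in transcription order (reverse of genomic order on
    the minus strand).
    """

    host_gene: str
    interval: GenomicInterval
    ordinal: int

    @property
    def intron_id(self) -> str:
        iv = self.interval
        return f"{self.host_gene}:{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}"

    @property
    def length(self) -> int:
        return self.interval.length

    def five_prime_boundary(self) -> int:
        """Genomic coordinate of the transcription-order 5' (exon-intron)
        boundary: the intron start on '+', the intron end on '-'."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end

    def three_prime_boundary(self) -> int:
        """Genomic coordinate of the transcription-order 3' (intron-exon)
        boundary."""
        iv = self.interval
        return iv.end if iv.strand == "+" else iv.start
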