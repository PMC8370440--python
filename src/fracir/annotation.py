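"""Annotation and genome I/O: GTF -> gene models -> introns; FASTA access.

GTF exon rows are assembled into :class:`~fracir.model.GeneModel` objects
and introns are derived as the gaps between consecutive exons of each
transcript, deduplicated per gene.  Field and attribute parsing of
individual GTF lines is delegated to :func:`gffutils.feature.feature_from_line`;
the assembly logic (coordinate conversion, sorting, intron derivation,
ordinal numbering) lives here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pyfaidx
from gffutils.feature import feature_from_line

from .model import GeneModel, GenomicInterval, IntronRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GtfParseError(ValueError):
    """Raised for malformed GTF input, naming the offending line."""


def read_gene_annotation(path: str | Path) -> dict[str, GeneModel]:
    """Read a GTF file into gene models keyed by ``gene_id``.

    Coordinates are converted from GTF's 1-based closed convention to
    0-based half-open.  Only ``exon`` features are used to build exon
    chains; ``gene``/``transcript`` rows contribute ``gene_name`` when
    present.  Single-exon transcripts are retained (they simply yield no
    introns).

    Raises
    ------
    GtfParseError
        On a malformed line (naming the 1-based line number) or an exon
        row lacking a ``transcript_id`` attribute.
    """
    genes: dict[str, GeneModel] = {}
    n_exons = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(
                    f"{path}: malformed GTF at line {lineno}: {exc}"
                ) from exc
            attrs = feat.attributes
            gene_id = (attrs.get("gene_id") or [None])[0]
            if gene_id is None:
                raise GtfParseError(
                    f"{path}: line {lineno}: feature without gene_id attribute"
                )
            gene_name = (attrs.get("gene_name") or [gene_id])[0]
            gene = genes.get(gene_id)
            if gene is None:
                gene = GeneModel(
                    gene_id=gene_id,
                    gene_name=gene_name,
                    chrom=feat.seqid,
                    strand=feat.strand,
                )
                genes[gene_id] = gene
            elif gene.gene_name == gene.gene_id and gene_name != gene_id:
                gene.gene_name = gene_name

            if feat.featuretype != "exon":
                continue
            tx_id = (attrs.get("transcript_id") or [None])[0]
            if tx_id is None:
                raise GtfParseError(
                    f"{path}: line {lineno}: exon without transcript_id parent"
                )
            if feat.seqid != gene.chrom or feat.strand != gene.strand:
                raise GtfParseError(
                    f"{path}: line {lineno}: exon of {gene_id} on "
                    f"{feat.seqid}({feat.strand}) conflicts with "
                    f"{gene.chrom}({gene.strand})"
                )
            # GTF 1-based closed -> 0-based half-open
            gene.transcripts.setdefault(tx_id, []).append(
                (feat.start - 1, feat.end)
            )
            n_exons += 1

    if n_exons == 0:
        logger.warning("%s: no exon features found; empty annotation", path)
        return {}

    # drop genes that carried no exons (bare gene rows) and sort exon chains
    genes = {g: m for g, m in genes.items() if m.transcripts}
    for gene in genes.values():
        for exons in gene.transcripts.values():
            exons.sort()
        gene.validate()
    return genes


def derive_introns(genes: Mapping[str, GeneModel] | Iterable[GeneModel]) -> list[IntronRecord]:
    """Derive introns as gaps between consecutive exons of each transcript.

    Identical gaps from multiple transcripts of the same gene collapse to
    a single :class:`IntronRecord`.  Ordinals follow transcription order
    (reverse of genomic order on the minus strand) over the gene's
    deduplicated intron set; an intron keeps the ordinal implied by the
    first transcript containing it when transcripts disagree, which for
    non-overlapping intron sets equals the transcription-order rank.
    Zero-length gaps (abutting exons) are skipped with a warning.
    """
    if isinstance(genes, Mapping):
        gene_iter = genes.values()
    else:
        gene_iter = genes
    records: list[IntronRecord] = []
    for gene in gene_iter:
        gaps: set[tuple[int, int]] = set()
        for tx_id, exons in gene.transcripts.items():
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 == e1:
                    logger.warning(
                        "%s/%s: abutting exons at %d, zero-length gap skipped",
                        gene.gene_id, tx_id, e1,
                    )
                    continue
                gaps.add((e1, s2))
        ordered = sorted(gaps, reverse=(gene.strand == "-"))
        for ordinal, (start, end) in enumerate(ordered, start=1):
            records.append(
                IntronRecord(
                    host_gene=gene.gene_id,
                    interval=GenomicInterval(gene.chrom, start, end, gene.strand),
                    ordinal=ordinal,
                )
            )
    return records


class GenomeSequence:
    """Random access to an (faidx-indexable) genome FASTA.

    Subsequences are returned uppercase; a minus-strand interval yields
    the reverse complement.
    """

    def __init__(self, path: str | Path):
        self._fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def chroms(self) -> list[str]:
        return list(self._fasta.keys())

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} absent from FASTA")
        return len(self._fasta[chrom])

    def fetch(self, interval: GenomicInterval) -> str:
        if interval.chrom not in self._fasta:
            raise KeyError(f"chromosome {interval.chrom!r} absent from FASTA")
        clen = len(self._fasta[interval.chrom])
        if interval.end > clen:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"extends past contig end ({clen})"
            )
        seq = str(self._fasta[interval.chrom][interval.start:interval.end])
        if interval.strand == "-":
            seq = reverse_complement(seq)
        return seq

    def close(self) -> None:
        self._fasta.close()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def introns_to_bed(introns: Iterable[IntronRecord], path: str | Path) -> None:
    """Write introns as BED6 (name = intron_id, score = 0)."""
    rows = sorted(introns, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    with open(path, "w") as out:
        for rec in rows:
            iv = rec.interval
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.intron_id}\t0\t{iv.strand}\n"
            )


def read_introns_bed(path: str | Path) -> list[IntronRecord]:
    """Re-read a BED6 written by :func:`introns_to_bed`."""
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected BED6")
            chrom, start, end, name, _score, strand = fields[:6]
            host_gene = name.split(":", 1)[0]
            # ordinal is not encoded in BED; recovered as 0 (unknown)
            records.append(
                IntronRecord(
                    host_gene=host_gene,
                    interval=GenomicInterval(chrom, int(start), int(end), strand),
                    ordinal=0,
                )
            )
    return records
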