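"""Junction-read counting and percent-intron-retention (PIR) estimation.

The retention estimator follows the junction-balance convention:

    PIR = 100 * mean(EI, IE) / (mean(EI, IE) + EE)

where EI/IE count reads contiguously spanning the transcription-order 5'
(exon-intron) and 3' (intron-exon) boundaries and EE counts split reads
whose skipped segment equals the intron exactly.  Averaging the two
boundary counts treats both boundaries symmetrically and is robust to
one noisy boundary.  Intron-body counts are recorded for QC but do not
enter PIR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .model import IntronRecord

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["EI", "IE", "EE", "body"]


def count_junction_reads(
    alignments: str | Path | pysam.AlignmentFile,
    introns: Iterable[IntronRecord],
    min_overhang: int = 8,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Count EI / IE / EE / intron-body reads per intron from SAM/BAM.

    Classification per (read, intron), with priority EE > EI/IE > body:

    * EE: the read has a skip (N) segment equal to the intron exactly;
    * EI (IE): a single aligned block covers the 5' (3') transcription-
      order boundary with >= ``min_overhang`` aligned bases on each side;
    * body: the read aligns fully inside the intron.

    A read contiguously spanning the whole intron is counted once, as EI.
    Reads on chromosomes absent from the annotation are skipped with a
    warning; unmapped reads are ignored.
    """
    intron_list = list(introns)
    trees: dict[str, IntervalTree] = {}
    for rec in intron_list:
        iv = rec.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, rec)

    counts = {
        rec.intron_id: dict.fromkeys(COUNT_COLUMNS, 0) for rec in intron_list
    }

    own = not isinstance(alignments, pysam.AlignmentFile)
    sam = (
        pysam.AlignmentFile(str(alignments), check_sq=False)
        if own else alignments
    )
    missing_chroms: set[str] = set()
    try:
        for read in sam:
            if read.is_unmapped:
                continue
            chrom = read.reference_name
            tree = trees.get(chrom)
            if tree is None:
                missing_chroms.add(chrom)
                continue
            blocks = read.get_blocks()
            if not blocks:
                continue
            rstart, rend = blocks[0][0], blocks[-1][1]
            # skipped (N) reference intervals between consecutive blocks
            skips = set()
            pos = read.reference_start
            for op, n in read.cigartuples:
                if op in (0, 7, 8, 2):  # M, =, X, D consume reference
                    pos += n
                elif op == 3:  # N
                    skips.add((pos, pos + n))
                    pos += n
            for hit in tree.overlap(rstart, rend):
                rec: IntronRecord = hit.data
                iv = rec.interval
                cls = None
                if (iv.start, iv.end) in skips:
                    cls = "EE"
                else:
                    fp = rec.five_prime_boundary()
                    tp = rec.three_prime_boundary()
                    for boundary, name in ((fp, "EI"), (tp, "IE")):
                        for bs, be in blocks:
                            if bs <= boundary - min_overhang and be >= boundary + min_overhang:
                                cls = name
                                break
                        if cls:
                            break
                    if cls is None and rstart >= iv.start and rend <= iv.end:
                        cls = "body"
                if cls:
                    counts[rec.intron_id][cls] += 1
    finally:
        if own:
            sam.close()
    if missing_chroms:
        logger.warning(
            "reads on chromosomes absent from annotation skipped: %s",
            ", ".join(sorted(missing_chroms)),
        )

    out = pd.DataFrame(
        [
            {"intron_id": iid, **vals}
            for iid, vals in counts.items()
        ]
    )
    if sample_id is not None:
        out.insert(0, "sample_id", sample_id)
    return out


def compute_pir(
    counts: pd.DataFrame,
    min_junction_reads: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PIR matrix (introns x samples) with a coverage mask.

    A cell is missing (NaN, ``coverage_ok`` False) when
    ``EI + IE + EE < min_junction_reads``.  Returns ``(pir, coverage_ok)``.
    """
    for col in ("EI", "IE", "EE"):
        if (counts[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    df = counts.copy()
    boundary = (df["EI"] + df["IE"]) / 2.0
    denom = boundary + df["EE"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["pir"] = 100.0 * boundary / denom
    df["pir"] = df["pir"].where(denom > 0)
    df["coverage_ok"] = (df["EI"] + df["IE"] + df["EE"]) >= min_junction_reads
    df.loc[~df["coverage_ok"], "pir"] = np.nan
    pir = df.pivot(index="intron_id", columns="sample_id", values="pir")
    cov = df.pivot(index="intron_id", columns="sample_id", values="coverage_ok")
    return pir, cov.fillna(False).astype(bool)


@dataclass
class ExpressionTable:
    """Raw counts plus CPM and log2(CPM+1) matrices (genes x samples)."""

    raw: pd.DataFrame
    cpm: pd.DataFrame
    log2: pd.DataFrame


def compute_expression(gene_counts: pd.DataFrame) -> ExpressionTable:
    """CPM-normalize a genes x samples raw count matrix; log2(x+1)."""
    totals = gene_counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"all-zero sample(s): {', '.join(map(str, zero.index))}"
        )
    cpm = gene_counts.div(totals, axis=1) * 1e6
    return ExpressionTable(
        raw=gene_counts, cpm=cpm, log2=np.log2(cpm + 1.0)
    )


def reliably_expressed(
    expr: ExpressionTable,
    design: pd.DataFrame,
    min_cpm: float = 1.0,
) -> pd.Index:
    """Genes with CPM >= threshold in every sample of at least one
    timepoint x fraction group."""
    keep = pd.Series(False, index=expr.cpm.index)
    for _, sub in design.groupby(["DIV", "fraction"]):
        cols = [c for c in sub["sample_id"] if c in expr.cpm.columns]
        if cols:
            keep |= (expr.cpm[cols] >= min_cpm).all(axis=1)
    return expr.cpm.index[keep]


def compute_irt_fraction(
    counts: pd.DataFrame,
    introns_of_interest: Sequence[str],
    design: pd.DataFrame,
    fraction: str = "cytoplasmic",
    timepoint: int | None = None,
) -> pd.DataFrame:
    """Per-genotype share of transcript signal carried by IRTs.

    For each intron and sample the IRT share is mean(EI, IE) /
    (mean(EI, IE) + EE), i.e. PIR / 100; the summary per genotype is the
    median and interquartile range of shares over the intron set in
    samples of the requested fraction (optionally one timepoint).
    """
    if len(introns_of_interest) == 0:
        raise ValueError("empty intron set")
    sel = design[design["fraction"] == fraction]
    if timepoint is not None:
        sel = sel[sel["DIV"] == timepoint]
    merged = counts.merge(
        sel[["sample_id", "genotype"]], on="sample_id", how="inner"
    )
    merged = merged[merged["intron_id"].isin(set(introns_of_interest))]
    boundary = (merged["EI"] + merged["IE"]) / 2.0
    denom = boundary + merged["EE"]
    merged = merged.assign(share=(boundary / denom).where(denom > 0))
    rows = []
    for genotype, sub in merged.groupby("genotype"):
        shares = sub["share"].dropna()
        rows.append({
            "genotype": genotype,
            "fraction": fraction,
            "n": len(shares),
            "median_share": shares.median(),
            "q1_share": shares.quantile(0.25),
            "q3_share": shares.quantile(0.75),
        })
    return pd.DataFrame(rows)
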