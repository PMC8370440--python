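"""Junction counting and PIR/expression estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracir.model import GenomicInterval, IntronRecord
from fracir.quant import (
    compute_expression,
    compute_irt_fraction,
    compute_pir,
    count_junction_reads,
    reliably_expressed,
)
from fracir.simulate import build_design, emit_alignments, SimulationConfig


def _counts_row(ei, ie, ee, sample="s1", intron="i1"):
    return pd.DataFrame({
        "sample_id": [sample], "intron_id": [intron],
        "EI": [ei], "IE": [ie], "EE": [ee], "body": [0],
    })


class TestComputePir:
    @pytest.mark.parametrize("ei,ie,ee,expected", [
        (10, 10, 10, 50.0),      # balanced counts
        (0, 0, 50, 0.0),         # fully spliced
        (30, 10, 20, 50.0),      # mean(30,10)=20 vs EE=20
        (10, 10, 0, 100.0),      # fully retained
    ])
    def test_formula(self, ei, ie, ee, expected):
        pir, _ = compute_pir(_counts_row(ei, ie, ee), min_junction_reads=1)
        assert pir.loc["i1", "s1"] == pytest.approx(expected)

    def test_low_coverage_cell_is_missing(self):
        pir, cov = compute_pir(_counts_row(2, 2, 2), min_junction_reads=10)
        assert np.isnan(pir.loc["i1", "s1"])
        assert not cov.loc["i1", "s1"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_pir(_counts_row(-1, 0, 5))

    @given(
        ei=st.integers(0, 50), ie=st.integers(0, 50), ee=st.integers(0, 50),
        k=st.integers(2, 9),
    )
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance(self, ei, ie, ee, k):
        if ei + ie + ee == 0:
            return
        p1, _ = compute_pir(_counts_row(ei, ie, ee), min_junction_reads=1)
        p2, _ = compute_pir(_counts_row(k * ei, k * ie, k * ee),
                            min_junction_reads=1)
        v1, v2 = p1.loc["i1", "s1"], p2.loc["i1", "s1"]
        assert (np.isnan(v1) and np.isnan(v2)) or v1 == pytest.approx(v2)

    def test_monotone_in_boundary_and_skip_counts(self):
        base, _ = compute_pir(_counts_row(10, 10, 10), min_junction_reads=1)
        more_ret, _ = compute_pir(_counts_row(12, 10, 10), min_junction_reads=1)
        more_spl, _ = compute_pir(_counts_row(10, 10, 12), min_junction_reads=1)
        assert more_ret.iloc[0, 0] > base.iloc[0, 0] > more_spl.iloc[0, 0]


class TestCountJunctionReads:
    @pytest.fixture
    def intron(self):
        return IntronRecord("G", GenomicInterval("chr1", 100, 200, "+"), 1)

    def _sam(self, tmp_path, reads):
        """reads: list of (start, cigar string) contiguous-coordinate reads."""
        import pysam
        path = tmp_path / "r.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10000}]}
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for i, (start, cigar) in enumerate(reads):
                seg = pysam.AlignedSegment(fh.header)
                seg.query_name = f"r{i}"
                seg.reference_id = 0
                seg.reference_start = start
                seg.mapping_quality = 255
                seg.cigarstring = cigar
                n_m = sum(
                    int(x) for x, op in
                    __import__("re").findall(r"(\d+)([MIDNS])", cigar)
                    if op in "MIS"
                )
                seg.query_sequence = "A" * n_m
                fh.write(seg)
        return path

    def test_insufficient_overhang_not_counted(self, tmp_path, intron):
        # aligned [95,120) over boundary 100: 5 exon-side bases < 8
        sam = self._sam(tmp_path, [(95, "25M")])
        got = count_junction_reads(sam, [intron]).iloc[0]
        assert got[["EI", "IE", "EE", "body"]].sum() == 0

    def test_exact_skip_counts_as_ee(self, tmp_path, intron):
        sam = self._sam(tmp_path, [(90, "10M100N10M")])
        got = count_junction_reads(sam, [intron]).iloc[0]
        assert got["EE"] == 1 and got["EI"] == 0

    def test_inexact_skip_not_ee(self, tmp_path, intron):
        sam = self._sam(tmp_path, [(90, "10M99N10M")])
        got = count_junction_reads(sam, [intron]).iloc[0]
        assert got["EE"] == 0

    def test_boundary_reads_and_body(self, tmp_path, intron):
        sam = self._sam(tmp_path, [
            (90, "20M"),    # EI: 10 each side of 100
            (190, "20M"),   # IE: 10 each side of 200
            (120, "30M"),   # body
        ])
        got = count_junction_reads(sam, [intron]).iloc[0]
        assert (got["EI"], got["IE"], got["body"]) == (1, 1, 1)

    def test_minus_strand_swaps_boundary_classes(self, tmp_path):
        intron = IntronRecord("G", GenomicInterval("chr1", 100, 200, "-"), 1)
        sam = self._sam(tmp_path, [(90, "20M")])  # genomic start boundary
        got = count_junction_reads(sam, [intron]).iloc[0]
        # genomic start is the 3' (intron-exon) boundary on the minus strand
        assert (got["EI"], got["IE"]) == (0, 1)

    def test_unknown_chromosome_skipped_with_warning(self, tmp_path, intron, caplog):
        import pysam
        path = tmp_path / "w.sam"
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": "chrZ", "LN": 1000}]}
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = "r0"
            seg.reference_id = 0
            seg.reference_start = 10
            seg.cigarstring = "20M"
            seg.query_sequence = "A" * 20
            fh.write(seg)
        with caplog.at_level("WARNING"):
            got = count_junction_reads(path, [intron])
        assert "chrZ" in caplog.text
        assert got[["EI", "IE", "EE", "body"]].to_numpy().sum() == 0

    def test_counter_matches_brute_force_oracle(self, tmp_path):
        """Synthetic SAM <= 500 reads: classes equal an independent
        per-read reimplementation of the three rules."""
        rng = np.random.default_rng(17)
        introns = [
            IntronRecord("G1", GenomicInterval("chr1", 1000, 1300, "+"), 1),
            IntronRecord("G1", GenomicInterval("chr1", 1600, 1700, "+"), 2),
            IntronRecord("G2", GenomicInterval("chr1", 3000, 3080, "-"), 1),
        ]
        reads = []
        for _ in range(400):
            start = int(rng.integers(900, 3200))
            kind = rng.integers(0, 3)
            if kind == 0:
                reads.append((start, f"{int(rng.integers(10, 40))}M"))
            elif kind == 1:
                iv = introns[int(rng.integers(0, 3))].interval
                a = int(rng.integers(4, 20))
                b = int(rng.integers(4, 20))
                reads.append((iv.start - a, f"{a}M{iv.length}N{b}M"))
            else:
                n1 = int(rng.integers(5, 15))
                gap = int(rng.integers(50, 400))
                n2 = int(rng.integers(5, 15))
                reads.append((start, f"{n1}M{gap}N{n2}M"))
        sam = self._sam(tmp_path, reads)
        got = count_junction_reads(sam, introns, min_overhang=8)
        got = got.set_index("intron_id")

        # independent oracle: re-derive blocks/skips from the cigar string
        import re
        oracle = {
            r.intron_id: {"EI": 0, "IE": 0, "EE": 0, "body": 0}
            for r in introns
        }
        for start, cigar in reads:
            blocks, skips = [], []
            pos = start
            for n, op in re.findall(r"(\d+)([MN])", cigar):
                n = int(n)
                if op == "M":
                    blocks.append((pos, pos + n))
                else:
                    skips.append((pos, pos + n))
                pos += n
            for rec in introns:
                iv = rec.interval
                cls = None
                if (iv.start, iv.end) in skips:
                    cls = "EE"
                else:
                    for boundary, name in (
                        (rec.five_prime_boundary(), "EI"),
                        (rec.three_prime_boundary(), "IE"),
                    ):
                        if any(bs <= boundary - 8 and be >= boundary + 8
                               for bs, be in blocks):
                            cls = name
                            break
                    if cls is None and blocks[0][0] >= iv.start \
                            and blocks[-1][1] <= iv.end:
                        cls = "body"
                if cls:
                    oracle[rec.intron_id][cls] += 1
        for rec in introns:
            for col in ("EI", "IE", "EE", "body"):
                assert got.loc[rec.intron_id, col] == oracle[rec.intron_id][col]


class TestExpression:
    def test_single_gene_cpm(self):
        raw = pd.DataFrame({"s1": [10 ** 6]}, index=["g1"])
        expr = compute_expression(raw)
        assert expr.cpm.loc["g1", "s1"] == pytest.approx(1e6)
        assert expr.log2.loc["g1", "s1"] == pytest.approx(np.log2(1e6 + 1))

    def test_even_split_symmetric(self):
        raw = pd.DataFrame({"s1": [50, 50]}, index=["g1", "g2"])
        expr = compute_expression(raw)
        assert (expr.cpm["s1"] == 5e5).all()

    def test_cpm_sums_to_million(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.integers(0, 500, (20, 4)),
                           columns=list("abcd"))
        expr = compute_expression(raw)
        assert expr.cpm.sum(axis=0).to_numpy() == pytest.approx(1e6)

    def test_all_zero_sample_rejected(self):
        raw = pd.DataFrame({"ok": [5], "bad": [0]}, index=["g1"])
        with pytest.raises(ValueError, match="bad"):
            compute_expression(raw)

    def test_reliably_expressed_by_enumeration(self):
        design = build_design(SimulationConfig(n_lines_control=1,
                                               n_lines_mutant=1,
                                               timepoints=(0,)))
        cols = design["sample_id"].tolist()  # 4 samples: 2 lines x 2 fractions
        raw = pd.DataFrame(
            {cols[0]: [100, 100, 1], cols[1]: [100, 1, 1],
             cols[2]: [100, 100, 1], cols[3]: [100, 1, 1]},
            index=["always", "nuclear_only", "never"],
        )
        expr = compute_expression(raw)
        kept = set(reliably_expressed(expr, design, min_cpm=5000))
        # brute force: a gene passes if some DIV x fraction group has all
        # samples >= threshold
        expected = set()
        for gene in raw.index:
            for _, grp in design.groupby(["DIV", "fraction"]):
                if (expr.cpm.loc[gene, grp["sample_id"]] >= 5000).all():
                    expected.add(gene)
        assert kept == expected


class TestIrtFraction:
    def _design(self):
        return pd.DataFrame({
            "sample_id": ["c_cyt", "m_cyt"],
            "line_id": ["c", "m"],
            "genotype": ["control", "mutant"],
            "DIV": [14, 14],
            "fraction": ["cytoplasmic", "cytoplasmic"],
        })

    def test_constant_pir_gives_constant_share(self):
        counts = pd.DataFrame({
            "sample_id": ["m_cyt"] * 3, "intron_id": list("abc"),
            "EI": [40, 40, 40], "IE": [40, 40, 40], "EE": [60, 60, 60],
            "body": 0, "gene_exonic": 0,
        })
        out = compute_irt_fraction(counts, list("abc"), self._design())
        mut = out[out.genotype == "mutant"].iloc[0]
        assert mut["median_share"] == pytest.approx(0.40)

    def test_zero_ee_gives_share_one(self):
        counts = pd.DataFrame({
            "sample_id": ["c_cyt"], "intron_id": ["a"],
            "EI": [10], "IE": [10], "EE": [0], "body": 0, "gene_exonic": 0,
        })
        out = compute_irt_fraction(counts, ["a"], self._design())
        assert out["median_share"].iloc[0] == 1.0

    def test_empty_intron_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_irt_fraction(pd.DataFrame(), [], self._design())
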