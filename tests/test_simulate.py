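"""Synthetic-data generator: determinism, planted effects, null behaviour."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fracir.model import GenomicInterval, IntronRecord
from fracir.quant import compute_pir, count_junction_reads
from fracir.simulate import (
    BOTH,
    CYTOPLASMIC,
    NUCLEAR,
    SimulationConfig,
    emit_alignments,
    plan_truth,
    simulate_annotation_and_genome,
    simulate_conservation_track,
    simulate_crosslink_tracks,
    simulate_fraction_counts,
    timepoint_ramp,
    truth_introns_as_records,
)


def test_config_validation_rejects_overcommitted_genes():
    cfg = SimulationConfig(n_genes=10, category_counts={NUCLEAR: 20})
    with pytest.raises(ValueError, match="exceed n_genes"):
        cfg.validate()


def test_config_validation_rejects_bad_leakage():
    with pytest.raises(ValueError, match="leakage"):
        SimulationConfig(leakage=1.0).validate()


def test_timepoint_ramp_is_triangular():
    cfg = SimulationConfig()
    assert timepoint_ramp(0, cfg) == 0.0
    assert timepoint_ramp(14, cfg) == 1.0
    assert timepoint_ramp(35, cfg) == 0.0
    assert 0 < timepoint_ramp(7, cfg) < 1


def test_planted_truth_partitions_categories(small_truth, small_config):
    introns = small_truth.introns
    assert introns["intron_id"].is_unique
    planted = introns[introns["category"] != ""]
    counts = planted["category"].value_counts().to_dict()
    assert counts == small_config.category_counts
    # each planted gene carries exactly one planted intron
    assert planted.groupby("host_gene").size().max() == 1


def test_degenerate_length_distributions_are_exact():
    cfg = SimulationConfig(
        n_genes=40,
        category_counts={NUCLEAR: 5, CYTOPLASMIC: 5, BOTH: 0},
        n_splicing_factors=4,
        length_dists={
            NUCLEAR: ("constant", 200), BOTH: ("constant", 1000),
            CYTOPLASMIC: ("constant", 2000), "": ("constant", 500),
        },
    )
    truth = plan_truth(cfg, 0)
    introns = truth.introns
    assert (introns.loc[introns.category == NUCLEAR, "length"] == 200).all()
    assert (introns.loc[introns.category == CYTOPLASMIC, "length"] == 2000).all()


def test_genome_gc_matches_target_within_binomial_bound(tmp_path):
    from fracir.annotation import GenomeSequence
    from fracir.features import compute_gc
    cfg = SimulationConfig(
        n_genes=12, category_counts={NUCLEAR: 3, BOTH: 0, CYTOPLASMIC: 0},
        n_splicing_factors=2, n_housekeeping=1,
        length_dists={NUCLEAR: ("constant", 10000), BOTH: ("constant", 1000),
                      CYTOPLASMIC: ("constant", 1000), "": ("constant", 500)},
        gc_targets={NUCLEAR: 0.7, BOTH: 0.45, CYTOPLASMIC: 0.4, "": 0.5},
    )
    _, fasta, truth = simulate_annotation_and_genome(cfg, tmp_path, 3)
    genome = GenomeSequence(fasta)
    for r in truth.introns[truth.introns.category == NUCLEAR].itertuples():
        seq = genome.fetch(GenomicInterval(r.chrom, r.start, r.end, r.strand))
        assert abs(compute_gc(seq) - 0.7) < 0.03


def test_annotation_and_genome_byte_identical_under_seed(tmp_path):
    cfg = SimulationConfig(
        n_genes=20, category_counts={NUCLEAR: 2, BOTH: 1, CYTOPLASMIC: 1},
        n_splicing_factors=2, n_housekeeping=1,
    )
    d1, d2 = tmp_path / "a", tmp_path / "b"
    g1, f1, _ = simulate_annotation_and_genome(cfg, d1, 9)
    g2, f2, _ = simulate_annotation_and_genome(cfg, d2, 9)
    assert g1.read_bytes() == g2.read_bytes()
    assert f1.read_bytes() == f2.read_bytes()


def test_counts_deterministic_under_seed(small_config, small_truth):
    c1, e1, d1 = simulate_fraction_counts(small_config, small_truth, 42)
    c2, e2, d2 = simulate_fraction_counts(small_config, small_truth, 42)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(e1, e2)
    pd.testing.assert_frame_equal(d1, d2)


def test_junction_reads_sum_to_depth_in_expectation(small_config, small_truth):
    counts, _, _ = simulate_fraction_counts(small_config, small_truth, 7)
    total = counts["EI"] + counts["IE"] + counts["EE"]
    # EI+IE+EE is exactly the NB depth draw; its mean is library_size
    assert total.mean() == pytest.approx(small_config.library_size, rel=0.02)


def test_null_simulation_pir_indistinguishable_between_genotypes():
    cfg = SimulationConfig(
        n_genes=150, category_counts={NUCLEAR: 0, BOTH: 0, CYTOPLASMIC: 0},
        n_splicing_factors=5, delta_pir=0.0, splicing_factor_downshift=0.0,
    )
    truth = plan_truth(cfg, 13)
    counts, _, design = simulate_fraction_counts(cfg, truth, 13)
    pir, _ = compute_pir(counts)
    at14 = design[(design.DIV == 14) & (design.fraction == "cytoplasmic")]
    mut = pir[at14.loc[at14.genotype == "mutant", "sample_id"]].mean(axis=1)
    ctl = pir[at14.loc[at14.genotype == "control", "sample_id"]].mean(axis=1)
    diff = (mut - ctl).dropna()
    p = stats.wilcoxon(diff).pvalue
    assert p > 0.01
    assert abs(diff.mean()) < 1.0


def test_planted_delta_recovered_at_deep_coverage():
    cfg = SimulationConfig(
        n_genes=60, category_counts={NUCLEAR: 0, BOTH: 0, CYTOPLASMIC: 20},
        n_splicing_factors=5, library_size=500.0, leakage=0.0, delta_pir=25.0,
    )
    truth = plan_truth(cfg, 21)
    counts, _, design = simulate_fraction_counts(cfg, truth, 21)
    pir, _ = compute_pir(counts)
    planted = truth.introns.loc[truth.introns.category == CYTOPLASMIC, "intron_id"]
    at14 = design[(design.DIV == 14) & (design.fraction == "cytoplasmic")]
    mut = pir.loc[planted, at14.loc[at14.genotype == "mutant", "sample_id"]]
    ctl = pir.loc[planted, at14.loc[at14.genotype == "control", "sample_id"]]
    delta = (mut.mean(axis=1) - ctl.mean(axis=1)).mean()
    assert delta == pytest.approx(25.0, abs=5.0)


class TestCrosslinkTracks:
    def test_non_enriched_rbps_never_receive_fold(self, small_config, small_truth):
        t1 = simulate_crosslink_tracks(small_config, small_truth, 5)
        null_cfg = dataclasses.replace(small_config, crosslink_fold=1.0)
        t0 = simulate_crosslink_tracks(null_cfg, small_truth, 5)
        for r in small_truth.rbps.itertuples():
            if not r.enriched:
                pd.testing.assert_frame_equal(t1[r.rbp_name], t0[r.rbp_name])

    def test_fold_realized_as_density_ratio(self, small_truth):
        cfg = SimulationConfig(
            n_genes=90, category_counts={NUCLEAR: 10, BOTH: 5, CYTOPLASMIC: 6},
            n_splicing_factors=8, n_housekeeping=2, n_rbps=15,
            n_enriched_rbps=5, crosslink_fold=4.0, crosslink_rate_per_kb=20.0,
        )
        tracks = simulate_crosslink_tracks(cfg, small_truth, 11)
        introns = small_truth.introns
        cyto = introns[introns.category == CYTOPLASMIC]
        bg = introns[introns.category == ""]
        rbp = small_truth.rbps[small_truth.rbps.enriched].rbp_name.iloc[0]
        ev = tracks[rbp]

        def density(sub):
            n = 0
            for r in sub.itertuples():
                n += ((ev.chrom == r.chrom) & (ev.start >= r.start)
                      & (ev.start < r.end)).sum()
            return n / sub.length.sum()

        ratio = density(cyto) / density(bg)
        assert ratio == pytest.approx(4.0, rel=0.25)


def test_conservation_track_mean_shift(small_config, small_truth):
    track = simulate_conservation_track(small_config, small_truth, 3)
    introns = small_truth.introns

    def mean_over(sub):
        vals = []
        for r in sub.itertuples():
            seg = track[(track.chrom == r.chrom) & (track.start >= r.start)
                        & (track.end <= r.end)]
            w = (seg.end - seg.start)
            vals.append((seg.value * w).sum() / w.sum())
        return np.mean(vals)

    m_cyto = mean_over(introns[introns.category == CYTOPLASMIC])
    m_bg = mean_over(introns[introns.category == ""].head(30))
    assert m_cyto - m_bg == pytest.approx(
        small_config.conservation_shift, abs=0.05
    )


class TestEmitAlignments:
    def _setup(self, small_truth):
        recs = truth_introns_as_records(small_truth)
        by_id = {r.intron_id: r for r in recs}
        chrom_len = (
            small_truth.genes.groupby("chrom")["end"].max() + 200
        ).to_dict()
        return recs, by_id, chrom_len

    def test_round_trip_recovers_planted_counts(self, small_truth, tmp_path):
        recs, by_id, chrom_len = self._setup(small_truth)
        rng = np.random.default_rng(2)
        sub = small_truth.introns.sample(8, random_state=3)
        table = pd.DataFrame({
            "intron_id": sub.intron_id.to_numpy(),
            "EI": rng.integers(0, 15, 8), "IE": rng.integers(0, 15, 8),
            "EE": rng.integers(0, 15, 8), "body": rng.integers(0, 8, 8),
        })
        sam = emit_alignments(table, by_id, chrom_len, tmp_path / "t.sam", seed=4)
        got = count_junction_reads(sam, recs).set_index("intron_id")
        for row in table.itertuples():
            for col in ("EI", "IE", "EE", "body"):
                assert got.loc[row.intron_id, col] == getattr(row, col)

    def test_empty_table_gives_valid_header_no_reads(self, small_truth, tmp_path):
        import pysam
        _, by_id, chrom_len = self._setup(small_truth)
        table = pd.DataFrame(columns=["intron_id", "EI", "IE", "EE", "body"])
        sam = emit_alignments(table, by_id, chrom_len, tmp_path / "e.sam", seed=0)
        with pysam.AlignmentFile(sam) as fh:
            assert len(fh.header["SQ"]) > 0
            assert sum(1 for _ in fh) == 0

    def test_intron_shorter_than_twice_overhang_rejected(self, tmp_path):
        rec = IntronRecord("G", GenomicInterval("chr1", 100, 110, "+"), 1)
        table = pd.DataFrame(
            {"intron_id": [rec.intron_id], "EI": [1], "IE": [0],
             "EE": [0], "body": [0]}
        )
        with pytest.raises(ValueError, match="overhang"):
            emit_alignments(
                table, {rec.intron_id: rec}, {"chr1": 1000},
                tmp_path / "x.sam", min_overhang=8, seed=0,
            )

    def test_sam_byte_identical_under_seed(self, small_truth, tmp_path):
        _, by_id, chrom_len = self._setup(small_truth)
        iid = small_truth.introns.intron_id.iloc[0]
        table = pd.DataFrame(
            {"intron_id": [iid], "EI": [3], "IE": [2], "EE": [5], "body": [7]}
        )
        s1 = emit_alignments(table, by_id, chrom_len, tmp_path / "1.sam", seed=6)
        s2 = emit_alignments(table, by_id, chrom_len, tmp_path / "2.sam", seed=6)
        assert s1.read_bytes() == s2.read_bytes()
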