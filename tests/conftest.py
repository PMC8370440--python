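"""Shared fixtures: tiny hand-written annotation and a small seeded
synthetic dataset reused across test modules."""

from __future__ import annotations

import pytest

from fracir.simulate import (
    BOTH,
    CYTOPLASMIC,
    NUCLEAR,
    SimulationConfig,
    plan_truth,
    simulate_fraction_counts,
)

TOY_GTF = """\
chr1\ttest\tgene\t1\t300\t.\t+\t.\tgene_id "GA"; gene_name "GENE_A";
chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "GA"; transcript_id "GA.t1";
chr1\ttest\texon\t201\t300\t.\t+\t.\tgene_id "GA"; transcript_id "GA.t1";
chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "GA"; transcript_id "GA.t2";
chr1\ttest\texon\t201\t250\t.\t+\t.\tgene_id "GA"; transcript_id "GA.t2";
chr2\ttest\texon\t1\t100\t.\t-\t.\tgene_id "GB"; transcript_id "GB.t1";
chr2\ttest\texon\t201\t400\t.\t-\t.\tgene_id "GB"; transcript_id "GB.t1";
chr2\ttest\texon\t501\t600\t.\t-\t.\tgene_id "GB"; transcript_id "GB.t1";
"""


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=90,
        category_counts={NUCLEAR: 10, BOTH: 5, CYTOPLASMIC: 6},
        n_splicing_factors=8,
        n_housekeeping=2,
        n_rbps=15,
        n_enriched_rbps=5,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return plan_truth(small_config, 101)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_truth):
    counts, expr, design = simulate_fraction_counts(small_config, small_truth, 101)
    return counts, expr, design
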