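"""Synthetic fractionated RNA-seq generator with planted ground truth.

Emulates the study design of a nuclear/cytoplasmic fractionation
time-course: several iPSC-like lines per genotype (default 4 control +
3 mutant), six timepoints (DIV 0-35), two fractions per sample, with
aberrant intron-retention events planted in three nucleocytoplasmic
categories (nuclear-predominant / both-compartments /
cytoplasmic-predominant, defaults 237/63/49).  The generator is
counts-first: junction counts are simulated directly from a molecule
model, and read-level SAM emission is an optional layer used to test the
junction counter end-to-end.

Molecule model
--------------
A transcript molecule either retains the intron (probability *p*, the
true PIR as a fraction) or is spliced.  A retained molecule presents two
junction-informative boundaries (EI and IE); a spliced molecule presents
one exon-exon junction (EE).  Junction reads therefore hit the retention
arm with probability ``rho = 2p / (1 + p)``, and the PIR estimator
``mean(EI, IE) / (mean(EI, IE) + EE)`` is consistent for *p*.

All outputs are fully determined by the seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .model import GenomicInterval, IntronRecord

# taxonomy category labels used throughout the package
NUCLEAR = "nuclear_predominant"
BOTH = "both_compartments"
CYTOPLASMIC = "cytoplasmic_predominant"
CATEGORIES = (NUCLEAR, BOTH, CYTOPLASMIC)

# Distribution spec: ("constant", v) | ("uniform", lo, hi)
#                  | ("lognormal", mean_log, sd_log) | ("beta", a, b)
Dist = tuple


def draw(dist: Dist, size, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "constant":
        return np.full(size, float(dist[1]))
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size)
    if kind == "lognormal":
        return rng.lognormal(dist[1], dist[2], size)
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size)
    raise ValueError(f"unknown distribution kind {kind!r}")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults encode the emulated design: 4 control and 3 mutant lines,
    six timepoints with the aberrant-retention effect ramping to a peak
    at DIV 14, planted category counts 237/63/49, a +25 percentage-point
    retention increase in the affected fraction(s), and 27 of 100 RBPs
    with 4-fold crosslink enrichment in cytoplasmic-category introns.
    """

    n_genes: int = 700
    introns_per_gene: tuple[int, int] = (2, 4)
    exon_length: int = 300
    n_lines_control: int = 4
    n_lines_mutant: int = 3
    timepoints: tuple[int, ...] = (0, 3, 7, 14, 22, 35)
    peak_timepoint: int = 14
    category_counts: dict = field(
        default_factory=lambda: {NUCLEAR: 237, BOTH: 63, CYTOPLASMIC: 49}
    )
    delta_pir: float = 25.0  # percentage points in affected fraction(s)
    baseline_pir_nuclear: Dist = ("beta", 3.0, 12.0)      # mean 0.20
    baseline_pir_cytoplasmic: Dist = ("beta", 2.0, 23.0)  # mean 0.08
    line_effect_sd: float = 0.0  # per-line jitter on baseline PIR (fraction)
    library_size: float = 100.0  # expected junction reads per intron per sample
    nb_dispersion: float = 0.05
    body_read_factor: float = 0.5
    leakage: float = 0.05  # nuclear contamination of the cytoplasmic fraction
    # intron cis features per category ('' = background, unplanted)
    length_dists: dict = field(default_factory=lambda: {
        NUCLEAR: ("lognormal", math.log(300.0), 0.35),
        BOTH: ("lognormal", math.log(1500.0), 0.35),
        CYTOPLASMIC: ("lognormal", math.log(2000.0), 0.35),
        "": ("lognormal", math.log(800.0), 0.6),
    })
    gc_targets: dict = field(default_factory=lambda: {
        NUCLEAR: 0.60, BOTH: 0.45, CYTOPLASMIC: 0.40, "": 0.50,
    })
    min_intron_length: int = 60
    conservation_base: float = 0.40
    conservation_shift: float = 0.25  # applied to cytoplasmic-only introns
    conservation_sd: float = 0.08
    conservation_segment: int = 50
    # RBP crosslink tracks
    n_rbps: int = 100
    n_enriched_rbps: int = 27
    crosslink_rate_per_kb: float = 20.0
    crosslink_fold: float = 4.0
    # expression structure
    n_splicing_factors: int = 72
    splicing_factor_downshift: float = -1.0  # cytoplasmic log2FC at the peak
    n_housekeeping: int = 5
    housekeeping_pir_nuclear: float = 0.30
    expr_log2_mean: float = 6.0
    expr_log2_sd: float = 1.0
    expr_timepoint_sd: float = 1.0
    expr_fraction_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        planted = sum(self.category_counts.values())
        if planted + self.n_housekeeping + self.n_splicing_factors > self.n_genes:
            raise ValueError(
                f"category_counts ({planted}) + housekeeping "
                f"({self.n_housekeeping}) + splicing factors "
                f"({self.n_splicing_factors}) exceed n_genes ({self.n_genes})"
            )
        if not (0.0 <= self.leakage < 1.0):
            raise ValueError("leakage must lie in [0, 1)")
        if self.n_enriched_rbps > self.n_rbps:
            raise ValueError("n_enriched_rbps exceeds n_rbps")
        if self.delta_pir < 0 or self.delta_pir > 100:
            raise ValueError("delta_pir must be in [0, 100] percentage points")
        if self.peak_timepoint not in self.timepoints:
            raise ValueError("peak_timepoint must be one of timepoints")
        unknown = set(self.category_counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in category_counts: {unknown}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        kwargs = dict(data)
        for key in ("introns_per_gene", "timepoints"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("baseline_pir_nuclear", "baseline_pir_cytoplasmic"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("length_dists",):
            if key in kwargs:
                kwargs[key] = {k: tuple(v) for k, v in kwargs[key].items()}
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PlantedTruth:
    """Ground truth of a simulation run.

    ``introns`` has one row per simulated intron (intron_id, host_gene,
    coordinates, length, gc_target, conservation_mean, category,
    per-fraction planted delta-PIR and baseline PIR); ``genes`` one row
    per gene; ``rbps`` one row per RBP with the enriched flag.
    """

    introns: pd.DataFrame
    genes: pd.DataFrame
    rbps: pd.DataFrame
    splicing_factors: list[str]
    housekeeping_genes: list[str]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.introns.to_csv(outdir / "truth_introns.tsv", sep="\t", index=False)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.rbps.to_csv(outdir / "truth_rbps.tsv", sep="\t", index=False)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # decorrelated streams per generator stage, all derived from one seed
    return np.random.default_rng([stream, seed])


def plan_truth(config: SimulationConfig, seed: int | None = None) -> PlantedTruth:
    """Lay out genes/introns on a toy genome and assign planted effects.

    The structural plan (coordinates, categories, cis features, RBP
    flags) is shared by every downstream simulator, so counts can be
    simulated without ever writing the genome.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed, 1)

    n = config.n_genes
    lo, hi = config.introns_per_gene
    n_introns_per_gene = rng.integers(lo, hi + 1, n)
    strands = rng.choice(["+", "-"], n)

    # role assignment: housekeeping, planted categories, splicing factors
    order = rng.permutation(n)
    roles = np.array([""] * n, dtype=object)
    is_hk = np.zeros(n, bool)
    is_sf = np.zeros(n, bool)
    pos = 0
    hk_idx = order[pos:pos + config.n_housekeeping]
    is_hk[hk_idx] = True
    pos += config.n_housekeeping
    for cat in CATEGORIES:
        k = config.category_counts.get(cat, 0)
        roles[order[pos:pos + k]] = cat
        pos += k
    sf_idx = order[pos:pos + config.n_splicing_factors]
    is_sf[sf_idx] = True

    gene_rows = []
    intron_rows = []
    genes_per_chrom = 50
    cursor = 200
    chrom_i = 0
    for gi in range(n):
        if gi > 0 and gi % genes_per_chrom == 0:
            chrom_i += 1
            cursor = 200
        chrom = f"chr{chrom_i + 1}"
        gene_id = f"G{gi + 1:04d}"
        strand = strands[gi]
        k_introns = int(n_introns_per_gene[gi])
        category = roles[gi]
        planted_pos = rng.integers(0, k_introns) if category else -1

        # intron lengths: planted intron from its category's distribution
        lens = []
        cats = []
        for j in range(k_introns):
            cat_j = category if j == planted_pos else ""
            length = int(round(draw(config.length_dists[cat_j], 1, rng)[0]))
            lens.append(max(length, config.min_intron_length))
            cats.append(cat_j)

        start = cursor
        exon_bounds = []
        intron_bounds = []
        p = start
        for j in range(k_introns + 1):
            exon_bounds.append((p, p + config.exon_length))
            p += config.exon_length
            if j < k_introns:
                intron_bounds.append((p, p + lens[j]))
                p += lens[j]
        gene_end = p
        cursor = gene_end + 200

        gene_rows.append({
            "gene_id": gene_id, "chrom": chrom, "start": start,
            "end": gene_end, "strand": strand, "n_introns": k_introns,
            "exonic_length": (k_introns + 1) * config.exon_length,
            "category": category, "is_housekeeping": bool(is_hk[gi]),
            "is_splicing_factor": bool(is_sf[gi]),
        })

        # per-intron baselines and planted deltas
        for j, (istart, iend) in enumerate(intron_bounds):
            cat_j = cats[j]
            gc = config.gc_targets[cat_j]
            cons = config.conservation_base + (
                config.conservation_shift if cat_j == CYTOPLASMIC else 0.0
            )
            if is_hk[gi]:
                base_nuc = config.housekeeping_pir_nuclear
                base_cyt = 0.0
            else:
                base_nuc = float(draw(config.baseline_pir_nuclear, 1, rng)[0])
                base_cyt = float(draw(config.baseline_pir_cytoplasmic, 1, rng)[0])
            d_nuc = config.delta_pir if cat_j in (NUCLEAR, BOTH) else 0.0
            d_cyt = config.delta_pir if cat_j in (CYTOPLASMIC, BOTH) else 0.0
            ordinal = j + 1 if strand == "+" else k_introns - j
            intron_rows.append({
                "intron_id": f"{gene_id}:{chrom}:{istart}-{iend}:{strand}",
                "host_gene": gene_id, "chrom": chrom, "start": istart,
                "end": iend, "strand": strand, "ordinal": ordinal,
                "length": iend - istart, "gc_target": gc,
                "conservation_mean": cons, "category": cat_j,
                "delta_pir_nuclear": d_nuc, "delta_pir_cytoplasmic": d_cyt,
                "base_pir_nuclear": base_nuc, "base_pir_cytoplasmic": base_cyt,
                "is_housekeeping": bool(is_hk[gi]),
            })

    genes = pd.DataFrame(gene_rows)
    introns = pd.DataFrame(intron_rows)

    rbp_names = ["SFPQ", "TDP43", "FUS"] + [
        f"RBP{i:03d}" for i in range(4, config.n_rbps + 1)
    ]
    rbp_names = rbp_names[: config.n_rbps]
    enriched = np.zeros(config.n_rbps, bool)
    enriched[: config.n_enriched_rbps] = True
    rbps = pd.DataFrame({"rbp_name": rbp_names, "enriched": enriched})

    return PlantedTruth(
        introns=introns,
        genes=genes,
        rbps=rbps,
        splicing_factors=sorted(genes.loc[genes.is_splicing_factor, "gene_id"]),
        housekeeping_genes=sorted(genes.loc[genes.is_housekeeping, "gene_id"]),
    )


def truth_introns_as_records(truth: PlantedTruth) -> list[IntronRecord]:
    """The planted intron set as IntronRecord objects."""
    return [
        IntronRecord(
            host_gene=r.host_gene,
            interval=GenomicInterval(r.chrom, r.start, r.end, r.strand),
            ordinal=int(r.ordinal),
        )
        for r in truth.introns.itertuples()
    ]


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), length, p=p)


def simulate_annotation_and_genome(
    config: SimulationConfig,
    outdir: str | Path,
    seed: int | None = None,
) -> tuple[Path, Path, PlantedTruth]:
    """Write a toy genome FASTA and matching GTF; return the planted truth.

    Intron sequences are drawn per-base with the category's GC target;
    exon sequences at GC 0.5.  Byte-identical output under a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    truth = plan_truth(config, seed)
    rng = _rng(seed, 2)

    chrom_len = {}
    for chrom, sub in truth.genes.groupby("chrom", sort=False):
        chrom_len[chrom] = int(sub["end"].max()) + 200

    # genome: exonic/intergenic background at GC 0.5, introns at target GC
    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fa:
        for chrom in sorted(chrom_len, key=lambda c: int(c[3:])):
            seq = _random_seq(chrom_len[chrom], 0.5, rng)
            sub = truth.introns[truth.introns.chrom == chrom]
            for r in sub.itertuples():
                if r.gc_target != 0.5:
                    seq[r.start:r.end] = _random_seq(r.length, r.gc_target, rng)
            fa.write(f">{chrom}\n")
            raw = seq.tobytes().decode()
            for i in range(0, len(raw), 80):
                fa.write(raw[i:i + 80] + "\n")

    gtf_path = outdir / "annotation.gtf"
    with open(gtf_path, "w") as gtf:
        for g in truth.genes.itertuples():
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                f'gene_name "{g.gene_id}";'
            )
            gattrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
            gtf.write(
                f"{g.chrom}\tfracir_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{gattrs}\n"
            )
            gtf.write(
                f"{g.chrom}\tfracir_sim\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            sub = truth.introns[truth.introns.host_gene == g.gene_id]
            bounds = sorted(
                [(r.start, r.end) for r in sub.itertuples()]
            )
            exon_starts = [g.start] + [e for _, e in bounds]
            exon_ends = [s for s, _ in bounds] + [g.end]
            for es, ee in zip(exon_starts, exon_ends):
                gtf.write(
                    f"{g.chrom}\tfracir_sim\texon\t{es + 1}\t{ee}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
    return gtf_path, fasta_path, truth


def timepoint_ramp(t: float, config: SimulationConfig) -> float:
    """Triangular effect profile: 0 at the first/last timepoint, 1 at the peak."""
    t0, t1 = min(config.timepoints), max(config.timepoints)
    peak = config.peak_timepoint
    if t <= peak:
        return (t - t0) / (peak - t0) if peak > t0 else 1.0
    return (t1 - t) / (t1 - peak) if t1 > peak else 1.0


def build_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: line, genotype, DIV timepoint, fraction."""
    rows = []
    lines = [(f"ctrl{i + 1}", "control") for i in range(config.n_lines_control)]
    lines += [(f"vcp{i + 1}", "mutant") for i in range(config.n_lines_mutant)]
    for line, genotype in lines:
        for t in config.timepoints:
            for fraction in ("nuclear", "cytoplasmic"):
                rows.append({
                    "sample_id": f"{line}_DIV{t}_{fraction}",
                    "line_id": line, "genotype": genotype,
                    "DIV": t, "fraction": fraction,
                })
    return pd.DataFrame(rows)


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts; var = m + dispersion * m^2."""
    mean = np.asarray(mean, float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_fraction_counts(
    config: SimulationConfig,
    truth: PlantedTruth,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate junction counts and gene expression for every sample.

    Returns ``(counts, expression, design)`` where ``counts`` is a long
    table (sample_id, intron_id, EI, IE, EE, body, gene_exonic),
    ``expression`` is genes x samples of raw counts and ``design`` is the
    sample sheet.  Mutant samples receive the planted delta-PIR in the
    category-appropriate fraction(s), scaled by the triangular timepoint
    ramp; cytoplasmic samples receive a ``leakage`` admixture of the
    nuclear retention signal; splicing-factor genes are down-shifted in
    mutant cytoplasm at the peak timepoint.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 3)
    design = build_design(config)
    introns = truth.introns
    n_i = len(introns)

    base = {
        "nuclear": introns["base_pir_nuclear"].to_numpy(),
        "cytoplasmic": introns["base_pir_cytoplasmic"].to_numpy(),
    }
    delta = {
        "nuclear": introns["delta_pir_nuclear"].to_numpy() / 100.0,
        "cytoplasmic": introns["delta_pir_cytoplasmic"].to_numpy() / 100.0,
    }

    # per-line jitter on baseline PIR (shared between fractions)
    line_ids = sorted(design["line_id"].unique())
    line_eff = {
        ln: (rng.normal(0.0, config.line_effect_sd, n_i)
             if config.line_effect_sd > 0 else np.zeros(n_i))
        for ln in line_ids
    }

    # gene expression structure on the log2 scale
    genes = truth.genes["gene_id"].to_numpy()
    g_rng = _rng(seed, 4)
    base_log2 = g_rng.normal(config.expr_log2_mean, config.expr_log2_sd, len(genes))
    tp_slope = g_rng.normal(0.0, config.expr_timepoint_sd, len(genes))
    frac_eff = g_rng.normal(0.0, config.expr_fraction_sd, len(genes))
    sf_mask = np.isin(genes, truth.splicing_factors)
    t_max = max(config.timepoints)

    expr_cols = {}
    counts_frames = []
    gene_index = pd.Index(genes)
    host_pos = gene_index.get_indexer(introns["host_gene"])

    for s in design.itertuples():
        ramp = timepoint_ramp(s.DIV, config)
        is_mut = s.genotype == "mutant"
        is_cyt = s.fraction == "cytoplasmic"

        def true_pir(fraction: str) -> np.ndarray:
            p = base[fraction] + line_eff[s.line_id]
            if is_mut:
                p = p + delta[fraction] * ramp
            return np.clip(p, 0.0, 0.97)

        p_here = true_pir(s.fraction)
        rho = 2.0 * p_here / (1.0 + p_here)
        if is_cyt and config.leakage > 0:
            p_nuc = true_pir("nuclear")
            rho_nuc = 2.0 * p_nuc / (1.0 + p_nuc)
            rho = (1.0 - config.leakage) * rho + config.leakage * rho_nuc
        p_eff = rho / (2.0 - rho)

        depth = _nb_counts(
            np.full(n_i, config.library_size), config.nb_dispersion, rng
        )
        ret = rng.binomial(depth, rho)
        ei = rng.binomial(ret, 0.5)
        ie = ret - ei
        ee = depth - ret
        body = rng.poisson(config.library_size * p_eff * config.body_read_factor)

        # expression
        log2_mean = base_log2 + tp_slope * (s.DIV / t_max)
        if is_cyt:
            log2_mean = log2_mean + frac_eff
        if is_mut and is_cyt and s.DIV == config.peak_timepoint:
            log2_mean = log2_mean + np.where(
                sf_mask, config.splicing_factor_downshift, 0.0
            )
        gexp = _nb_counts(2.0 ** log2_mean, config.nb_dispersion, rng)
        expr_cols[s.sample_id] = gexp

        counts_frames.append(pd.DataFrame({
            "sample_id": s.sample_id,
            "intron_id": introns["intron_id"],
            "EI": ei, "IE": ie, "EE": ee, "body": body,
            "gene_exonic": gexp[host_pos],
        }))

    counts = pd.concat(counts_frames, ignore_index=True)
    expression = pd.DataFrame(expr_cols, index=gene_index)
    expression.index.name = "gene_id"
    return counts, expression, design


def simulate_crosslink_tracks(
    config: SimulationConfig,
    truth: PlantedTruth,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Poisson crosslink events per RBP, enriched in cytoplasmic introns.

    Background density ``crosslink_rate_per_kb`` everywhere; multiplied
    by ``crosslink_fold`` inside cytoplasmic-category introns for the
    enriched RBPs only.  Events are 1-bp intervals on the intron strand.
    """
    seed = config.seed if seed is None else seed
    introns = truth.introns
    lengths = introns["length"].to_numpy()
    starts = introns["start"].to_numpy()
    chroms = introns["chrom"].to_numpy()
    strands = introns["strand"].to_numpy()
    is_cyto = (introns["category"] == CYTOPLASMIC).to_numpy()
    tracks: dict[str, pd.DataFrame] = {}
    for r in truth.rbps.itertuples():
        # one substream per RBP: a track depends only on its own parameters
        rng = np.random.default_rng([5, seed, r.Index])
        rate = np.full(len(introns), config.crosslink_rate_per_kb / 1000.0)
        if r.enriched:
            rate = np.where(is_cyto, rate * config.crosslink_fold, rate)
        n_events = rng.poisson(rate * lengths)
        rep = np.repeat(np.arange(len(introns)), n_events)
        pos = starts[rep] + (rng.random(len(rep)) * lengths[rep]).astype(np.int64)
        df = pd.DataFrame({
            "chrom": chroms[rep],
            "start": pos,
            "end": pos + 1,
            "name": r.rbp_name,
            "score": 1,
            "strand": strands[rep],
        })
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        tracks[r.rbp_name] = df
    return tracks


def write_crosslink_beds(tracks: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rbp in sorted(tracks):
        path = outdir / f"{rbp}.bed"
        tracks[rbp].to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


def simulate_conservation_track(
    config: SimulationConfig,
    truth: PlantedTruth,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-segment conservation scores over intron bodies (bedGraph rows).

    Scores are clipped Gaussians around each intron's target mean, which
    is ``conservation_base`` plus ``conservation_shift`` for
    cytoplasmic-predominant-category introns.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 6)
    seg = config.conservation_segment
    rows = []
    for r in truth.introns.itertuples():
        for s in range(r.start, r.end, seg):
            e = min(s + seg, r.end)
            val = float(np.clip(
                rng.normal(r.conservation_mean, config.conservation_sd), 0.0, 1.0
            ))
            rows.append((r.chrom, s, e, round(val, 4)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False)


def emit_alignments(
    counts: pd.DataFrame,
    introns: Mapping[str, IntronRecord],
    chrom_lengths: Mapping[str, int],
    path: str | Path,
    min_overhang: int = 8,
    seed: int = 0,
    read_anchor: int = 25,
) -> Path:
    """Write a SAM file realizing a junction-count table exactly.

    For each intron row (columns ``intron_id, EI, IE, EE, body``): EE
    reads are split alignments whose N segment skips the intron exactly;
    EI/IE reads are contiguous alignments straddling the transcription-
    order 5'/3' boundary with at least ``min_overhang`` aligned bases on
    each side; body reads lie fully inside the intron.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": int(chrom_lengths[c])}
            for c in sorted(chrom_lengths, key=str)
        ],
    }
    tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}

    reads = []  # (chrom, start, cigartuples, qname)

    def jitter(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1)) if hi > lo else lo

    for row in counts.itertuples():
        rec = introns[row.intron_id]
        iv = rec.interval
        ilen = iv.length
        total = int(row.EI + row.IE + row.EE + getattr(row, "body", 0))
        if total == 0:
            continue
        if ilen < 2 * min_overhang:
            raise ValueError(
                f"{row.intron_id}: intron length {ilen} < 2 x overhang "
                f"({2 * min_overhang}); cannot realize requested reads"
            )
        fp = rec.five_prime_boundary()
        tp = rec.three_prime_boundary()

        def contiguous(boundary: int, n: int, cls: str) -> None:
            # aligned bases on each side: [ov, ov+12], intron side < ilen
            for i in range(int(n)):
                left = min_overhang + jitter(0, 12)
                right = min_overhang + jitter(0, 12)
                if boundary == iv.start:  # intron on the right
                    right = min(right, ilen - 1)
                    start = boundary - left
                else:  # boundary == iv.end, intron on the left
                    left = min(left, ilen - 1)
                    start = boundary - left
                start = max(start, 0)
                length = left + right
                reads.append((
                    iv.chrom, start, [(0, length)],
                    f"{row.intron_id}|{cls}|{i}",
                ))

        contiguous(fp, row.EI, "EI")
        contiguous(tp, row.IE, "IE")
        for i in range(int(row.EE)):
            a = min_overhang + jitter(0, 12)
            b = min_overhang + jitter(0, 12)
            start = max(iv.start - a, 0)
            a = iv.start - start
            reads.append((
                iv.chrom, start,
                [(0, a), (3, ilen), (0, b)],
                f"{row.intron_id}|EE|{i}",
            ))
        n_body = int(getattr(row, "body", 0))
        if n_body:
            blen = min(2 * min_overhang + 10, ilen)
            for i in range(n_body):
                off = jitter(0, ilen - blen)
                reads.append((
                    iv.chrom, iv.start + off, [(0, blen)],
                    f"{row.intron_id}|body|{i}",
                ))

    reads.sort(key=lambda r: (r[0], r[1], r[3]))
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for chrom, start, cigartuples, qname in reads:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = qname
            seg.flag = 0
            seg.reference_id = tid[chrom]
            seg.reference_start = start
            seg.mapping_quality = 255
            seg.cigartuples = cigartuples
            match_len = sum(n for op, n in cigartuples if op == 0)
            seg.query_sequence = "A" * match_len
            sam.write(seg)
    return path
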