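"""Cis sequence features of retained introns and category comparisons.

Features per intron: length (nt), GC content (fraction internally,
percent in outputs), and mean per-base conservation from a bedGraph
track.  Categories are compared pairwise — and against the background of
all introns in genes hosting at least one aberrant IR event — with
two-sided Mann-Whitney tests, BH-corrected across comparisons.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import GenomicInterval, IntronRecord
from .simulate import CATEGORIES

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


def compute_gc(sequence: str) -> float:
    """GC fraction of a sequence; N bases are excluded from numerator and
    denominator.  Returns NaN when no A/C/G/T bases remain."""
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-IUPAC character(s) in sequence: {sorted(bad)}")
    effective = len(seq) - seq.count("N")
    if effective == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / effective


class ConservationTrack:
    """Per-base conservation scores loaded from a bedGraph file.

    Segments are stored per chromosome sorted by start; the mean over an
    interval is the length-weighted mean of overlapping segment values,
    invariant to how the track is segmented.
    """

    def __init__(self, segments: pd.DataFrame):
        required = {"chrom", "start", "end", "value"}
        if not required.issubset(segments.columns):
            raise ValueError(f"conservation track needs columns {required}")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in segments.groupby("chrom"):
            sub = sub.sort_values("start")
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(int),
                sub["end"].to_numpy(int),
                sub["value"].to_numpy(float),
            )

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "ConservationTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
        )
        return cls(df)

    def mean_over(self, interval: GenomicInterval) -> tuple[float, float]:
        """(mean score over covered bases, covered fraction of the interval).

        Mean is NaN when the track covers < 50% of the interval (or the
        chromosome is absent, with a warning).
        """
        data = self._by_chrom.get(interval.chrom)
        if data is None:
            logger.warning(
                "conservation track has no chromosome %s", interval.chrom
            )
            return float("nan"), 0.0
        starts, ends, values = data
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        total = 0.0
        covered = 0
        for i in range(lo, len(starts)):
            if starts[i] >= interval.end:
                break
            ov = min(ends[i], interval.end) - max(starts[i], interval.start)
            if ov > 0:
                total += ov * values[i]
                covered += ov
        frac = covered / interval.length
        mean = total / covered if frac >= 0.5 else float("nan")
        return mean, frac


def compute_conservation(
    track: ConservationTrack, interval: GenomicInterval
) -> float:
    """Mean per-base conservation over an interval (NaN under 50% coverage)."""
    mean, _ = track.mean_over(interval)
    return mean


def compute_cis_features(
    introns: Iterable[IntronRecord],
    genome=None,
    conservation: ConservationTrack | None = None,
) -> pd.DataFrame:
    """Length, GC and conservation per intron.

    ``genome`` is a :class:`fracir.annotation.GenomeSequence`; GC and
    conservation are NaN when the respective input is absent.
    """
    rows = []
    for rec in introns:
        gc = np.nan
        cons = np.nan
        cov = np.nan
        if genome is not None:
            gc = compute_gc(genome.fetch(rec.interval))
        if conservation is not None:
            cons, cov = conservation.mean_over(rec.interval)
        rows.append({
            "intron_id": rec.intron_id,
            "host_gene": rec.host_gene,
            "length": rec.length,
            "gc": gc,
            "gc_percent": gc * 100.0 if np.isfinite(gc) else np.nan,
            "conservation": cons,
            "conservation_coverage": cov,
        })
    return pd.DataFrame(rows)


def background_intron_set(
    calls: pd.DataFrame, all_introns: Iterable[IntronRecord]
) -> list[IntronRecord]:
    """All introns of genes hosting >= 1 aberrant IR event (the white-box
    baseline); recomputed from the taxonomy calls, not user-supplied."""
    host_of = {}
    for rec in all_introns:
        host_of.setdefault(rec.host_gene, []).append(rec)
    target_genes = {iid.split(":", 1)[0] for iid in calls["intron_id"]}
    out = []
    for gene in sorted(target_genes):
        out.extend(host_of.get(gene, []))
    return out


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 12
) -> tuple[float, float]:
    """Two-sided Mann-Whitney (U statistic of x over y, p-value).

    Exact enumeration when both groups are small and untied; normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) == 1:  # fully tied: no evidence either way
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_categories(
    features: pd.DataFrame,
    calls: pd.DataFrame,
    background: pd.DataFrame | None = None,
    feature_cols: Sequence[str] = ("length", "gc", "conservation"),
    min_group: int = 3,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of cis features between groups.

    Groups are the three taxonomy categories plus (optionally) the
    background set; BH correction is applied across all comparisons.
    Group pairs where either side has fewer than ``min_group`` finite
    values are skipped with a flag.
    """
    feat = features.set_index("intron_id")
    groups: dict[str, pd.DataFrame] = {}
    for cat in CATEGORIES:
        ids = calls.loc[calls["category"] == cat, "intron_id"]
        groups[cat] = feat.reindex(ids.to_numpy())
    if background is not None:
        groups["background"] = (
            background.set_index("intron_id")
            if "intron_id" in background.columns else background
        )

    rows = []
    for feature in feature_cols:
        for g1, g2 in itertools.combinations(groups, 2):
            v1 = groups[g1][feature].dropna().to_numpy()
            v2 = groups[g2][feature].dropna().to_numpy()
            if len(v1) < min_group or len(v2) < min_group:
                rows.append({
                    "feature": feature, "group1": g1, "group2": g2,
                    "n1": len(v1), "n2": len(v2), "U": np.nan, "p": np.nan,
                    "median1": np.nan, "median2": np.nan,
                    "direction": "skipped", "skipped": True,
                })
                continue
            u, p = mann_whitney(v1, v2)
            m1, m2 = float(np.median(v1)), float(np.median(v2))
            direction = "none" if m1 == m2 else (
                f"{g1}>{g2}" if m1 > m2 else f"{g2}>{g1}"
            )
            rows.append({
                "feature": feature, "group1": g1, "group2": g2,
                "n1": len(v1), "n2": len(v2), "U": u, "p": p,
                "median1": m1, "median2": m2,
                "direction": direction, "skipped": False,
            })
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(
            out.loc[tested, "p"], method="fdr_bh"
        )[1]
    return out


def expression_coupling(
    expr,
    calls: pd.DataFrame,
    design: pd.DataFrame,
    host_map: Mapping[str, str] | None = None,
    timepoint: int | None = None,
    min_group: int = 3,
) -> pd.DataFrame:
    """Host-gene expression shift per taxonomy category and fraction.

    For each category x fraction cell: distribution of host-gene log2FC
    (difference of genotype means of log2(CPM+1)), a sign test against
    zero, BH across the six cells.  Host genes missing from the
    expression table are excluded and counted.
    """
    log2 = expr.log2 if hasattr(expr, "log2") else expr
    if host_map is None:
        host_map = {
            iid: iid.split(":", 1)[0] for iid in calls["intron_id"]
        }
    if timepoint is None and "timepoint" in calls.columns and len(calls):
        timepoint = int(calls["timepoint"].iloc[0])
    rows = []
    for fraction in ("nuclear", "cytoplasmic"):
        stratum = design[design["fraction"] == fraction]
        if timepoint is not None:
            stratum = stratum[stratum["DIV"] == timepoint]
        ctrl_cols = [
            s for s in stratum.loc[stratum["genotype"] == "control", "sample_id"]
            if s in log2.columns
        ]
        mut_cols = [
            s for s in stratum.loc[stratum["genotype"] == "mutant", "sample_id"]
            if s in log2.columns
        ]
        for cat in CATEGORIES:
            hosts = [
                host_map.get(iid)
                for iid in calls.loc[calls["category"] == cat, "intron_id"]
            ]
            present = sorted({h for h in hosts if h in log2.index})
            n_missing = len({h for h in hosts if h is not None}) - len(present)
            if not present or not ctrl_cols or not mut_cols:
                continue
            lfc = (
                log2.loc[present, mut_cols].mean(axis=1)
                - log2.loc[present, ctrl_cols].mean(axis=1)
            )
            nonzero = lfc[lfc != 0]
            if len(present) >= min_group and len(nonzero):
                p = stats.binomtest(
                    int((nonzero < 0).sum()), len(nonzero), 0.5,
                    alternative="two-sided",
                ).pvalue
            else:
                p = np.nan
            rows.append({
                "category": cat, "fraction": fraction,
                "n_genes": len(present), "n_missing": n_missing,
                "median_log2fc": float(lfc.median()),
                "q1_log2fc": float(lfc.quantile(0.25)),
                "q3_log2fc": float(lfc.quantile(0.75)),
                "sign_test_p": p,
            })
    out = pd.DataFrame(rows)
    if len(out):
        tested = out["sign_test_p"].notna()
        out["q"] = np.nan
        if tested.any():
            out.loc[tested, "q"] = multipletests(
                out.loc[tested, "sign_test_p"], method="fdr_bh"
            )[1]
    return out
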