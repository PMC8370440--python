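"""RBP crosslink-event enrichment over retained introns.

The enrichment score of RBP *r* in intron *i* is a pseudocounted log2
density ratio against a background intron set:

    density_i   = weighted events with midpoint inside i / length_i   [events/kb]
    background  = median density over the background introns
    score_i     = log2((density_i + c) / (background + c)),  c = 0.1 events/kb

The midpoint rule treats crosslink events as point-like and avoids
double counting at intron boundaries.  Events on the opposite strand of
the intron are ignored when the BED carries strand information;
strandless BEDs match both strands.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import IntronRecord
from .simulate import BOTH, CATEGORIES, CYTOPLASMIC, NUCLEAR

logger = logging.getLogger(__name__)

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_crosslink_bed(path: str | Path, rbp_name: str | None = None) -> pd.DataFrame:
    """Read one BED(3-6) file of crosslink events.

    The RBP name defaults to the file stem; a BED name column is kept as
    event metadata.  Event weight is 1 per interval.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df["rbp_name"] = rbp_name or Path(path).stem
    df["weight"] = 1.0
    return df


def read_crosslink_beds(paths: Iterable[str | Path]) -> dict[str, pd.DataFrame]:
    return {Path(p).stem: read_crosslink_bed(p) for p in paths}


def score_crosslink_enrichment(
    track: pd.DataFrame,
    introns: Sequence[IntronRecord],
    background_introns: Sequence[IntronRecord],
    pseudocount: float = 0.1,
    background_stat: str = "median",
) -> pd.Series:
    """Per-intron log2 crosslink-density enrichment for one RBP track.

    ``track`` is a BED-like DataFrame (chrom, start, end[, strand],
    weight).  Densities are in events/kb; the background statistic is
    the median (config-switchable to mean) density over
    ``background_introns``.
    """
    if len(background_introns) == 0:
        raise ValueError("background intron set is empty")

    def densities(recs: Sequence[IntronRecord]) -> np.ndarray:
        out = np.zeros(len(recs))
        if len(track) == 0:
            return out
        mid = ((track["start"].to_numpy() + track["end"].to_numpy()) // 2)
        chroms = track["chrom"].to_numpy()
        strands = (
            track["strand"].to_numpy()
            if "strand" in track.columns
            else np.full(len(track), ".")
        )
        weights = (
            track["weight"].to_numpy()
            if "weight" in track.columns
            else np.ones(len(track))
        )
        by_chrom = {}
        for c in np.unique(chroms):
            m = chroms == c
            order = np.argsort(mid[m], kind="stable")
            by_chrom[c] = (mid[m][order], strands[m][order], weights[m][order])
        for i, rec in enumerate(recs):
            data = by_chrom.get(rec.interval.chrom)
            if data is None:
                continue
            mids, strs, wts = data
            lo = np.searchsorted(mids, rec.interval.start, side="left")
            hi = np.searchsorted(mids, rec.interval.end - 1, side="right")
            if hi <= lo:
                continue
            sel_str = strs[lo:hi]
            sel_wts = wts[lo:hi]
            match = (sel_str == ".") | (sel_str == rec.interval.strand)
            out[i] = sel_wts[match].sum()
        lengths = np.array([r.length for r in recs], float)
        return 1000.0 * out / lengths

    d = densities(introns)
    d_bg = densities(background_introns)
    bg = float(np.median(d_bg) if background_stat == "median" else np.mean(d_bg))
    scores = np.log2((d + pseudocount) / (bg + pseudocount))
    return pd.Series(scores, index=[r.intron_id for r in introns], name="score")


def build_enrichment_matrix(
    tracks: Mapping[str, pd.DataFrame],
    introns: Sequence[IntronRecord],
    background_introns: Sequence[IntronRecord],
    pseudocount: float = 0.1,
    background_stat: str = "median",
) -> pd.DataFrame:
    """Intron x RBP enrichment-score matrix (heat-map ready)."""
    cols = {}
    for rbp in sorted(tracks):
        cols[rbp] = score_crosslink_enrichment(
            tracks[rbp], introns, background_introns,
            pseudocount=pseudocount, background_stat=background_stat,
        )
    matrix = pd.DataFrame(cols)
    matrix.index.name = "intron_id"
    return matrix


def rank_rbps_by_category(
    matrix: pd.DataFrame,
    calls: pd.DataFrame,
    q_threshold: float = 0.05,
    min_group: int = 3,
) -> pd.DataFrame:
    """Rank RBPs by differential binding to cytoplasmic- vs
    nuclear-predominant introns.

    Per RBP: two-sided Mann-Whitney of cytoplasmic-category scores vs
    nuclear-category scores (secondarily vs both-compartments), BH
    across RBPs; an RBP is ``enriched`` iff q < threshold and the
    cytoplasmic median exceeds the nuclear median.  Sorted by effect
    size (difference of medians), ties broken deterministically by name.
    """
    ids_by_cat = {
        cat: [
            i for i in calls.loc[calls["category"] == cat, "intron_id"]
            if i in matrix.index
        ]
        for cat in CATEGORIES
    }
    for cat in (CYTOPLASMIC, NUCLEAR):
        if len(ids_by_cat[cat]) < min_group:
            raise ValueError(
                f"category {cat} has fewer than {min_group} introns with scores"
            )
    rows = []
    for rbp in matrix.columns:
        cyt = matrix.loc[ids_by_cat[CYTOPLASMIC], rbp].dropna()
        nuc = matrix.loc[ids_by_cat[NUCLEAR], rbp].dropna()
        both = matrix.loc[ids_by_cat[BOTH], rbp].dropna()
        if cyt.nunique() <= 1 and nuc.nunique() <= 1 and cyt.median() == nuc.median():
            p = 1.0
            u = len(cyt) * len(nuc) / 2.0
        else:
            res = stats.mannwhitneyu(cyt, nuc, alternative="two-sided")
            u, p = float(res.statistic), float(res.pvalue)
        if len(both) >= min_group and (cyt.nunique() > 1 or both.nunique() > 1):
            p_both = float(
                stats.mannwhitneyu(cyt, both, alternative="two-sided").pvalue
            )
        else:
            p_both = np.nan
        rows.append({
            "rbp_name": rbp,
            "median_cytoplasmic": float(cyt.median()),
            "median_nuclear": float(nuc.median()),
            "median_both": float(both.median()) if len(both) else np.nan,
            "effect_size": float(cyt.median() - nuc.median()),
            "U": u,
            "p": p,
            "p_vs_both": p_both,
        })
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enriched"] = (out["q"] < q_threshold) & (out["effect_size"] > 0)
    out = out.sort_values(
        ["effect_size", "rbp_name"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out


def per_category_rbp_profile(
    matrix: pd.DataFrame,
    calls: pd.DataFrame,
    rbp_name: str,
) -> pd.DataFrame:
    """Score distribution of one RBP across the three categories, with
    pairwise Mann-Whitney tests."""
    if rbp_name not in matrix.columns:
        raise KeyError(
            f"unknown RBP {rbp_name!r}; available: "
            f"{', '.join(map(str, matrix.columns))}"
        )
    scores = {
        cat: matrix.loc[
            [i for i in calls.loc[calls["category"] == cat, "intron_id"]
             if i in matrix.index],
            rbp_name,
        ].dropna()
        for cat in CATEGORIES
    }
    for cat, s in scores.items():
        if len(s) == 0:
            raise ValueError(f"category {cat} has no scored introns")
    rows = []
    import itertools
    for c1, c2 in itertools.combinations(CATEGORIES, 2):
        s1, s2 = scores[c1], scores[c2]
        if s1.nunique() <= 1 and s2.nunique() <= 1 and s1.median() == s2.median():
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(s1, s2, alternative="two-sided").pvalue)
        rows.append({
            "rbp_name": rbp_name, "group1": c1, "group2": c2,
            "n1": len(s1), "n2": len(s2),
            "median1": float(s1.median()), "median2": float(s2.median()),
            "p": p,
        })
    return pd.DataFrame(rows)
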