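"""Differential intron retention between genotypes, per fraction and timepoint.

The per-intron test is a two-sided Fisher exact test on pooled junction
counts.  The retention arm pools EI + IE across lines; the splicing arm
counts 2 x EE by default, because one retained molecule contributes two
boundary reads where one spliced molecule contributes a single exon-exon
read — doubling balances the per-molecule evidence (switchable to raw
EE).  Counts are pooled across lines for the test; a separate per-line
sign-consistency filter guards against single-line artifacts.
Benjamini-Hochberg correction is applied within each fraction x
timepoint stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EVENT_CLASSES = ("IR", "AltEx", "Alt5", "Alt3", "MIC")


class FisherResult(NamedTuple):
    p: float
    degenerate: bool


def fisher_count_test(
    retention_ctrl: int,
    splicing_ctrl: int,
    retention_mut: int,
    splicing_mut: int,
) -> FisherResult:
    """Two-sided Fisher exact p for the 2x2 retention/splicing table.

    The table is ``[[retention_ctrl, splicing_ctrl],
    [retention_mut, splicing_mut]]``.  A table with any zero margin is
    uninformative: p = 1 is returned with ``degenerate=True``.
    """
    a, b, c, d = retention_ctrl, splicing_ctrl, retention_mut, splicing_mut
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        return FisherResult(1.0, True)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return FisherResult(float(min(p, 1.0)), False)


@dataclass
class ScanThresholds:
    """Significance criteria for the differential scan (all config-exposed)."""

    q_threshold: float = 0.05
    min_abs_delta_pir: float = 10.0   # percentage points
    min_coverage: int = 20            # pooled junction reads per genotype
    consistency_fraction: float = 2.0 / 3.0
    double_ee: bool = True            # splicing arm = 2*EE (else raw EE)


def _pooled_pir(ei: np.ndarray, ie: np.ndarray, ee: np.ndarray) -> np.ndarray:
    boundary = (ei + ie) / 2.0
    denom = boundary + ee
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, 100.0 * boundary / denom, np.nan)


def differential_ir_scan(
    pir: pd.DataFrame,
    counts: pd.DataFrame,
    design: pd.DataFrame,
    thresholds: ScanThresholds | None = None,
) -> pd.DataFrame:
    """Scan every fraction x timepoint stratum for aberrant IR events.

    Parameters
    ----------
    pir : DataFrame
        introns x samples PIR matrix (percent; NaN below coverage), used
        for the per-line sign-consistency filter.
    counts : DataFrame
        Long junction-count table (sample_id, intron_id, EI, IE, EE).
    design : DataFrame
        Sample sheet with sample_id, line_id, genotype, DIV, fraction.

    Returns one row per intron x fraction x timepoint with pooled PIR
    per genotype, delta-PIR (mutant - control), Fisher p, BH q (within
    the stratum), direction, the number of sign-consistent line pairs
    and the significance call.  Strata with a genotype entirely missing
    are skipped with a warning.
    """
    import logging
    logger = logging.getLogger(__name__)
    th = thresholds or ScanThresholds()
    results = []
    for (fraction, div), stratum in design.groupby(["fraction", "DIV"]):
        ctrl = stratum[stratum["genotype"] == "control"]
        mut = stratum[stratum["genotype"] == "mutant"]
        if ctrl.empty or mut.empty:
            logger.warning(
                "stratum %s/DIV%s: a genotype is entirely missing; skipped",
                fraction, div,
            )
            continue
        sub = counts[counts["sample_id"].isin(set(stratum["sample_id"]))]
        merged = sub.merge(
            stratum[["sample_id", "genotype"]], on="sample_id"
        )
        pooled = merged.groupby(["intron_id", "genotype"])[
            ["EI", "IE", "EE"]
        ].sum().unstack("genotype")
        # introns must be covered in both genotypes
        for g in ("control", "mutant"):
            if ("EI", g) not in pooled.columns:
                pooled[("EI", g)] = 0
        ei_c = pooled[("EI", "control")].fillna(0).to_numpy(int)
        ie_c = pooled[("IE", "control")].fillna(0).to_numpy(int)
        ee_c = pooled[("EE", "control")].fillna(0).to_numpy(int)
        ei_m = pooled[("EI", "mutant")].fillna(0).to_numpy(int)
        ie_m = pooled[("IE", "mutant")].fillna(0).to_numpy(int)
        ee_m = pooled[("EE", "mutant")].fillna(0).to_numpy(int)
        intron_ids = pooled.index.to_numpy()

        pir_c = _pooled_pir(ei_c, ie_c, ee_c)
        pir_m = _pooled_pir(ei_m, ie_m, ee_m)
        delta = pir_m - pir_c
        cov_c = ei_c + ie_c + ee_c
        cov_m = ei_m + ie_m + ee_m
        covered = (cov_c >= th.min_coverage) & (cov_m >= th.min_coverage)

        ee_mult = 2 if th.double_ee else 1
        pvals = np.full(len(intron_ids), np.nan)
        degenerate = np.zeros(len(intron_ids), bool)
        for i in np.nonzero(covered)[0]:
            res = fisher_count_test(
                int(ei_c[i] + ie_c[i]), int(ee_mult * ee_c[i]),
                int(ei_m[i] + ie_m[i]), int(ee_mult * ee_m[i]),
            )
            pvals[i] = res.p
            degenerate[i] = res.degenerate
        qvals = np.full(len(intron_ids), np.nan)
        tested = np.isfinite(pvals)
        if tested.any():
            qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

        # per-line sign consistency from the PIR matrix
        ctrl_cols = [c for c in ctrl["sample_id"] if c in pir.columns]
        mut_cols = [c for c in mut["sample_id"] if c in pir.columns]
        n_consistent = np.zeros(len(intron_ids), int)
        n_pairs_valid = np.zeros(len(intron_ids), int)
        if ctrl_cols and mut_cols:
            sub_pir = pir.reindex(intron_ids)
            pc = sub_pir[ctrl_cols].to_numpy()          # (I, nc)
            pm = sub_pir[mut_cols].to_numpy()           # (I, nm)
            diffs = pm[:, None, :] - pc[:, :, None]     # (I, nc, nm)
            valid = np.isfinite(diffs)
            sign_target = np.sign(delta)[:, None, None]
            agree = valid & (np.sign(diffs) == sign_target) & (diffs != 0)
            n_consistent = agree.sum(axis=(1, 2))
            n_pairs_valid = valid.sum(axis=(1, 2))

        need = np.ceil(th.consistency_fraction * n_pairs_valid)
        consistent_ok = (n_pairs_valid > 0) & (n_consistent >= need)
        significant = (
            tested
            & (qvals < th.q_threshold)
            & (np.abs(delta) >= th.min_abs_delta_pir)
            & covered
            & consistent_ok
        )
        results.append(pd.DataFrame({
            "intron_id": intron_ids,
            "fraction": fraction,
            "timepoint": div,
            "pir_control": pir_c,
            "pir_mutant": pir_m,
            "delta_pir": delta,
            "p": pvals,
            "q": qvals,
            "direction": np.where(delta > 0, "included", "skipped"),
            "n_lines_consistent": n_consistent,
            "n_line_pairs": n_pairs_valid,
            "coverage_ok": covered,
            "degenerate": degenerate,
            "significant": significant,
        }))
    if not results:
        return pd.DataFrame(columns=[
            "intron_id", "fraction", "timepoint", "pir_control", "pir_mutant",
            "delta_pir", "p", "q", "direction", "n_lines_consistent",
            "n_line_pairs", "coverage_ok", "degenerate", "significant",
        ])
    return pd.concat(results, ignore_index=True)


def significant_union(results: pd.DataFrame) -> pd.DataFrame:
    """Events significant in >= 1 timepoint, per fraction.

    The reported direction and delta-PIR are taken from the event's most
    significant (smallest q) timepoint.
    """
    sig = results[results["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=[
            "fraction", "intron_id", "direction", "best_timepoint",
            "best_q", "delta_pir", "n_timepoints",
        ])
    rows = []
    for (fraction, intron_id), sub in sig.groupby(["fraction", "intron_id"]):
        best = sub.loc[sub["q"].idxmin()]
        rows.append({
            "fraction": fraction,
            "intron_id": intron_id,
            "direction": best["direction"],
            "best_timepoint": best["timepoint"],
            "best_q": best["q"],
            "delta_pir": best["delta_pir"],
            "n_timepoints": len(sub),
        })
    return pd.DataFrame(rows)


def splicing_event_census(
    diff_results: pd.DataFrame,
    preclassified: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-stratum event tallies by class and direction.

    IR events come from the differential scan (significant rows); other
    splicing classes (AltEx, Alt5, Alt3, MIC) may be supplied as a
    pre-classified table (event_id, class, direction, fraction,
    timepoint) — they are tallied, never re-quantified.
    """
    frames = []
    sig = diff_results[diff_results["significant"]]
    if not sig.empty:
        ir = sig.groupby(["fraction", "timepoint", "direction"]).size()
        ir = ir.rename("n").reset_index()
        ir.insert(2, "event_class", "IR")
        frames.append(ir)
    if preclassified is not None and not preclassified.empty:
        bad = set(preclassified["class"]) - set(EVENT_CLASSES)
        if bad:
            raise ValueError(f"unknown event class label(s): {sorted(bad)}")
        other = preclassified.groupby(
            ["fraction", "timepoint", "class", "direction"]
        ).size().rename("n").reset_index()
        other = other.rename(columns={"class": "event_class"})
        frames.append(other)
    if not frames:
        return pd.DataFrame(
            columns=["fraction", "timepoint", "event_class", "direction",
                     "n", "proportion"]
        )
    census = pd.concat(frames, ignore_index=True)
    totals = census.groupby(["fraction", "timepoint"])["n"].transform("sum")
    census["proportion"] = census["n"] / totals
    return census.sort_values(
        ["fraction", "timepoint", "event_class", "direction"]
    ).reset_index(drop=True)


def splicing_factor_shift(
    expr,
    factor_genes,
    design: pd.DataFrame,
    fraction: str = "cytoplasmic",
) -> pd.DataFrame:
    """Distribution of per-factor-gene log2FC (mutant vs control) per timepoint.

    log2FC is the difference of genotype means of log2(CPM+1) in the
    requested fraction.  A one-sided sign test asks whether the median
    shift is below zero.  Factor genes absent from the expression table
    are reported in the ``missing_genes`` column.
    """
    factor_genes = list(factor_genes)
    if not factor_genes:
        raise ValueError("empty splicing-factor gene list")
    log2 = expr.log2 if hasattr(expr, "log2") else expr
    present = [g for g in factor_genes if g in log2.index]
    missing = sorted(set(factor_genes) - set(present))
    rows = []
    sel = design[design["fraction"] == fraction]
    for div, stratum in sel.groupby("DIV"):
        ctrl_cols = [
            s for s in stratum.loc[stratum["genotype"] == "control", "sample_id"]
            if s in log2.columns
        ]
        mut_cols = [
            s for s in stratum.loc[stratum["genotype"] == "mutant", "sample_id"]
            if s in log2.columns
        ]
        if not ctrl_cols or not mut_cols:
            continue
        lfc = (
            log2.loc[present, mut_cols].mean(axis=1)
            - log2.loc[present, ctrl_cols].mean(axis=1)
        )
        nonzero = lfc[lfc != 0]
        n_neg = int((nonzero < 0).sum())
        if len(nonzero):
            p_sign = stats.binomtest(
                n_neg, len(nonzero), 0.5, alternative="greater"
            ).pvalue
        else:
            p_sign = 1.0
        rows.append({
            "timepoint": div,
            "fraction": fraction,
            "n_genes": len(present),
            "median_log2fc": lfc.median(),
            "q1_log2fc": lfc.quantile(0.25),
            "q3_log2fc": lfc.quantile(0.75),
            "sign_test_p": p_sign,
            "missing_genes": ",".join(missing),
        })
    return pd.DataFrame(rows)
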