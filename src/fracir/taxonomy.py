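"""Nucleocytoplasmic taxonomy of aberrant intron-retention events.

Significant inclusion events at one timepoint are partitioned by where
they reach significance: nuclear fraction only -> nuclear-predominant;
cytoplasmic only -> cytoplasmic-predominant; both -> both-compartments.
The rule-based classifier stands in for manual curation; an optional
override list reproduces hand curation when available.

Category-wise retention in external PIR datasets (e.g. whole-cell motor
neuron RNA-seq from other disease mutations) is compared between
genotypes with a line-stratified permutation test: per-line mean
retention over the category's introns is the exchangeable unit and
genotype labels are permuted across lines (exhaustively when feasible).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .simulate import BOTH, CATEGORIES, CYTOPLASMIC, NUCLEAR


def peak_timepoint(results: pd.DataFrame) -> int:
    """Timepoint with the most significant IR events (both fractions)."""
    sig = results[results["significant"]]
    if sig.empty:
        raise ValueError("no significant events; cannot pick a peak timepoint")
    return int(sig.groupby("timepoint").size().idxmax())


def classify_compartment(
    results: pd.DataFrame,
    timepoint: int | None = None,
    overrides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify significant inclusion events at one timepoint.

    Parameters
    ----------
    results : DataFrame
        Output of :func:`fracir.diff.differential_ir_scan`; must cover
        both fractions at the chosen timepoint.
    timepoint : int, optional
        Defaults to the timepoint with the most significant events.
    overrides : DataFrame, optional
        Curation overrides with columns intron_id, action
        (``include``/``exclude``) and, for includes, category.

    Returns one row per classified intron: category, per-fraction
    delta-PIR and q, and a low-confidence flag for introns wholly
    untested in one fraction.
    """
    if timepoint is None:
        timepoint = peak_timepoint(results)
    at_t = results[results["timepoint"] == timepoint]
    if set(at_t["fraction"].unique()) != {"nuclear", "cytoplasmic"}:
        raise ValueError(
            f"timepoint {timepoint}: results must cover both fractions"
        )
    nuc = at_t[at_t["fraction"] == "nuclear"].set_index("intron_id")
    cyt = at_t[at_t["fraction"] == "cytoplasmic"].set_index("intron_id")

    sig_nuc = set(nuc.index[nuc["significant"] & (nuc["direction"] == "included")])
    sig_cyt = set(cyt.index[cyt["significant"] & (cyt["direction"] == "included")])

    excluded: set[str] = set()
    forced: dict[str, str] = {}
    if overrides is not None and len(overrides):
        for row in overrides.itertuples():
            if row.action == "exclude":
                excluded.add(row.intron_id)
            elif row.action == "include":
                forced[row.intron_id] = row.category
            else:
                raise ValueError(f"unknown override action {row.action!r}")

    rows = []
    for intron_id in sorted((sig_nuc | sig_cyt | set(forced)) - excluded):
        if intron_id in forced:
            category = forced[intron_id]
            if category not in CATEGORIES:
                raise ValueError(f"override category {category!r} unknown")
        elif intron_id in sig_nuc and intron_id in sig_cyt:
            category = BOTH
        elif intron_id in sig_nuc:
            category = NUCLEAR
        else:
            category = CYTOPLASMIC
        in_nuc = intron_id in nuc.index
        in_cyt = intron_id in cyt.index
        rows.append({
            "intron_id": intron_id,
            "category": category,
            "timepoint": timepoint,
            "nuclear_delta_pir": nuc.loc[intron_id, "delta_pir"] if in_nuc else np.nan,
            "cytoplasmic_delta_pir": cyt.loc[intron_id, "delta_pir"] if in_cyt else np.nan,
            "nuclear_q": nuc.loc[intron_id, "q"] if in_nuc else np.nan,
            "cytoplasmic_q": cyt.loc[intron_id, "q"] if in_cyt else np.nan,
            "low_confidence": not (in_nuc and in_cyt),
        })
    return pd.DataFrame(rows, columns=[
        "intron_id", "category", "timepoint", "nuclear_delta_pir",
        "cytoplasmic_delta_pir", "nuclear_q", "cytoplasmic_q",
        "low_confidence",
    ])


def category_counts(calls: pd.DataFrame) -> dict[str, int]:
    return {cat: int((calls["category"] == cat).sum()) for cat in CATEGORIES}


def _line_permutation_p(
    line_means: pd.Series,
    genotypes: pd.Series,
    max_exhaustive: int = 20000,
    n_random: int = 5000,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Two-sided permutation p for a genotype difference of line means.

    Lines are the exchangeable units.  All ``C(n, k)`` genotype
    assignments are enumerated when feasible, otherwise a seeded random
    subset is drawn.  Returns (p, observed statistic, n permutations).
    """
    values = line_means.to_numpy(float)
    is_mut = (genotypes == "mutant").to_numpy()
    n, k = len(values), int(is_mut.sum())
    if k == 0 or k == n:
        raise ValueError("permutation test needs lines of both genotypes")
    obs = values[is_mut].mean() - values[~is_mut].mean()
    n_comb = math.comb(n, k)
    count = 0
    total = 0
    if n_comb <= max_exhaustive:
        for combo in itertools.combinations(range(n), k):
            mask = np.zeros(n, bool)
            mask[list(combo)] = True
            stat = values[mask].mean() - values[~mask].mean()
            if abs(stat) >= abs(obs) - 1e-12:
                count += 1
            total += 1
    else:
        rng = np.random.default_rng(seed)
        count = 1  # identity permutation
        total = 1
        for _ in range(n_random):
            mask = np.zeros(n, bool)
            mask[rng.choice(n, k, replace=False)] = True
            stat = values[mask].mean() - values[~mask].mean()
            if abs(stat) >= abs(obs) - 1e-12:
                count += 1
            total += 1
    return count / total, float(obs), total


def category_retention_profile(
    external_pir: pd.DataFrame,
    external_design: pd.DataFrame,
    calls: pd.DataFrame,
    id_map: dict[str, str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Category-wise genotype comparison in an external PIR dataset.

    Parameters
    ----------
    external_pir : DataFrame
        Introns x samples PIR-like table (percent).
    external_design : DataFrame
        sample_id, line_id, genotype for the external samples.
    calls : DataFrame
        Taxonomy calls keyed by intron_id (mapped through ``id_map`` if
        the external table uses different identifiers).

    For each category — and the pooled set of all classified introns —
    reports per-genotype distribution summaries, the median paired
    (mutant-mean minus control-mean) per-intron difference, and a
    line-stratified permutation p-value.
    """
    ids = calls["intron_id"]
    if id_map is not None:
        ids = ids.map(lambda x: id_map.get(x, x))
    mapped = pd.DataFrame({
        "intron_id": ids.to_numpy(), "category": calls["category"].to_numpy()
    })
    found = mapped["intron_id"].isin(external_pir.index)
    if found.mean() < 0.5:
        raise ValueError(
            f"only {found.sum()}/{len(mapped)} classified introns found in "
            "the external table; supply an intron ID mapping"
        )
    mapped = mapped[found]

    sample_to_line = external_design.set_index("sample_id")["line_id"]
    line_geno = external_design.drop_duplicates("line_id").set_index(
        "line_id")["genotype"]

    groups = {"all_classified": mapped["intron_id"].tolist()}
    for cat in CATEGORIES:
        groups[cat] = mapped.loc[mapped["category"] == cat, "intron_id"].tolist()

    rows = []
    for name, intron_ids in groups.items():
        if not intron_ids:
            continue
        sub = external_pir.loc[intron_ids]
        cols = [c for c in sub.columns if c in sample_to_line.index]
        sub = sub[cols]
        # per-line mean retention over the group's introns
        by_line = sub.T.groupby(sample_to_line.loc[cols]).mean().mean(axis=1)
        genos = line_geno.loc[by_line.index]
        p, stat, n_perm = _line_permutation_p(by_line, genos, seed=seed)
        mut_cols = [c for c in cols if line_geno[sample_to_line[c]] == "mutant"]
        ctl_cols = [c for c in cols if line_geno[sample_to_line[c]] == "control"]
        paired_diff = sub[mut_cols].mean(axis=1) - sub[ctl_cols].mean(axis=1)
        rows.append({
            "group": name,
            "n_introns": len(intron_ids),
            "median_pir_control": sub[ctl_cols].stack().median(),
            "median_pir_mutant": sub[mut_cols].stack().median(),
            "median_paired_difference": paired_diff.median(),
            "line_mean_difference": stat,
            "permutation_p": p,
            "n_permutations": n_perm,
        })
    return pd.DataFrame(rows)
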