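"""Fractionation QC and global expression structure.

Leakage of nuclear RNA into the cytoplasmic fraction is assessed from
housekeeping genes as the ratio of intronic to exonic signal per
fraction (the sequencing analogue of an intron/exon qPCR assay), with
the cytoplasmic/nuclear ratio of ratios as the normalized leakage.
Global structure comes from an SVD of the gene-centered expression
matrix and from hierarchical clustering of samples (1 - Spearman
correlation, complete linkage, serialized as Newick).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from skbio.tree import TreeNode

from .model import IntronRecord


def fractionation_leakage(
    counts: pd.DataFrame,
    introns: Sequence[IntronRecord],
    housekeeping_genes: Iterable[str],
    design: pd.DataFrame,
    exonic_length: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Intron/exon signal ratios for housekeeping genes, per line.

    Per housekeeping gene and sample: intronic signal = sum of
    intron-body counts / total intron length; exonic signal =
    gene_exonic count / exonic length (length 1 if unknown, affecting
    only the scale, not the cross-fraction normalization).  Returns one
    row per gene x line with the nuclear and cytoplasmic ratios and
    ``normalized_leakage`` = cytoplasmic / nuclear ratio (NaN when the
    nuclear ratio is 0).
    """
    housekeeping = list(housekeeping_genes)
    by_gene: dict[str, list[IntronRecord]] = {}
    for rec in introns:
        by_gene.setdefault(rec.host_gene, []).append(rec)
    for gene in housekeeping:
        if not by_gene.get(gene):
            raise ValueError(f"housekeeping gene {gene} has no introns")

    meta = design.set_index("sample_id")
    rows = []
    for gene in housekeeping:
        recs = by_gene[gene]
        ids = {r.intron_id for r in recs}
        intron_len = sum(r.length for r in recs)
        exon_len = (exonic_length or {}).get(gene, 1)
        sub = counts[counts["intron_id"].isin(ids)]
        per_sample = sub.groupby("sample_id").agg(
            body_sum=("body", "sum"), gene_exonic=("gene_exonic", "first")
        )
        per_sample["ratio"] = (
            (per_sample["body_sum"] / intron_len)
            / (per_sample["gene_exonic"] / exon_len).replace(0, np.nan)
        )
        per_sample = per_sample.join(meta[["line_id", "fraction", "DIV", "genotype"]])
        for (line, div), lsub in per_sample.groupby(["line_id", "DIV"]):
            nuc = lsub.loc[lsub["fraction"] == "nuclear", "ratio"]
            cyt = lsub.loc[lsub["fraction"] == "cytoplasmic", "ratio"]
            nuc_ratio = float(nuc.iloc[0]) if len(nuc) else np.nan
            cyt_ratio = float(cyt.iloc[0]) if len(cyt) else np.nan
            norm = (
                cyt_ratio / nuc_ratio
                if np.isfinite(nuc_ratio) and nuc_ratio > 0 else np.nan
            )
            rows.append({
                "gene": gene, "line_id": line, "DIV": div,
                "genotype": lsub["genotype"].iloc[0],
                "nuclear_ratio": nuc_ratio,
                "cytoplasmic_ratio": cyt_ratio,
                "normalized_leakage": norm,
            })
    return pd.DataFrame(rows)


def svd_structure(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    scale_unit_variance: bool = False,
    n_components: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SVD of the gene-centered expression matrix.

    Parameters
    ----------
    expr : DataFrame
        genes x samples matrix (e.g. log2 CPM), complete (no NaN).
    scale_unit_variance : bool
        Also divide each gene row by its standard deviation.

    Returns ``(variance, coordinates)``: per-component variance
    fractions, and per-sample coordinates on the first components
    annotated with the design labels.
    """
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    mat = expr.to_numpy(float)
    mat = mat - mat.mean(axis=1, keepdims=True)
    if scale_unit_variance:
        sd = mat.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        mat = mat / sd
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    variance = pd.DataFrame({
        "component": np.arange(1, len(s) + 1),
        "singular_value": s,
        "variance_fraction": frac,
    })
    k = min(n_components, vt.shape[0])
    coords = pd.DataFrame(
        vt[:k].T * s[:k],
        index=expr.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    coords = coords.join(design.set_index("sample_id"), how="left")
    coords.index.name = "sample_id"
    return variance, coords.reset_index()


def sample_clustering(
    expr: pd.DataFrame,
) -> tuple[pd.DataFrame, str]:
    """Hierarchical clustering of samples.

    Distance = 1 - Spearman rank correlation between sample expression
    vectors; complete-linkage agglomeration.  Returns the distance
    matrix and the dendrogram as a Newick string (branch lengths from
    linkage heights).
    """
    const = expr.std(axis=0) == 0
    if const.any():
        raise ValueError(
            "constant expression vector(s): "
            + ", ".join(map(str, expr.columns[const]))
        )
    rho = spearmanr(expr.to_numpy()).statistic
    if np.isscalar(rho):  # two samples
        rho = np.array([[1.0, rho], [rho, 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    dist_df = pd.DataFrame(dist, index=expr.columns, columns=expr.columns)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    tree = TreeNode.from_linkage_matrix(linkage, list(map(str, expr.columns)))
    newick = str(tree).strip()
    return dist_df, newick
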