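"""Rank-abundance (Whittaker) analysis, abundance binning, and CV.

A Whittaker curve plots each gene's share of total group-mean expression
against its abundance rank (1 = most abundant). Disease mechanisms leave
distinct signatures: loss of low-abundance genes depresses the curve's
tail, amplification of dominant genes lifts its head. Abundance bins
(low / medium / high tertiles of grand-mean abundance) support prevalence
breakdowns of gene sets, and the percent coefficient of variation
(100*sd/mean, sample sd) summarises expression variability.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix, GroupDesign, ensure_tpm

BIN_LABELS_3 = ["low", "medium", "high"]


def whittaker_curve(matrix: ExpressionMatrix, design: GroupDesign,
                    group: str) -> pd.DataFrame:
    """Rank-abundance curve from group-mean TPM.

    Returns a tidy frame (rank, gene_id, share) sorted by descending
    share; ties are broken by gene id for determinism. Shares sum to 1.
    """
    matrix = ensure_tpm(matrix)
    samples = design.samples_in(group)
    if not samples:
        raise ValueError(f"group {group!r} has no samples")
    means = matrix.tpm[samples].mean(axis=1)
    total = means.sum()
    if total <= 0:
        raise ValueError(f"group {group!r} has zero total expression")
    share = (means / total).rename("share")
    ordered = share.reset_index().rename(columns={"index": "gene_id"})
    ordered.columns = ["gene_id", "share"]
    ordered = ordered.sort_values(["share", "gene_id"],
                                  ascending=[False, True], kind="mergesort")
    ordered.insert(0, "rank", np.arange(1, len(ordered) + 1))
    ordered["group"] = group
    return ordered.reset_index(drop=True)


def rank_correlation(group_a_means, group_b_means) -> float:
    """Spearman rank correlation between two per-gene abundance vectors.

    Average ranks on ties; equals 1 - 6*sum(d^2)/(n(n^2-1)) for tie-free
    input. Requires the same gene universe in both vectors.
    """
    a = pd.Series(group_a_means)
    b = pd.Series(group_b_means)
    if isinstance(group_a_means, pd.Series) and isinstance(group_b_means, pd.Series):
        if set(a.index) != set(b.index):
            raise ValueError("inputs must cover the same gene universe")
        b = b.reindex(a.index)
    elif len(a) != len(b):
        raise ValueError("inputs must have the same length")
    if len(a) < 3:
        raise ValueError("rank correlation needs at least 3 genes")
    rho = scipy.stats.spearmanr(a.to_numpy(), b.to_numpy()).statistic
    return float(rho)


def abundance_bins(matrix: ExpressionMatrix, n_bins: int = 3) -> pd.Series:
    """Assign each gene to an abundance bin by grand-mean TPM tertiles.

    Genes are ordered by (mean, gene_id) — the id tie-break makes boundary
    assignment deterministic — and split into ``n_bins`` near-equal rank
    slices. For 3 bins the labels are low / medium / high.
    """
    matrix = ensure_tpm(matrix)
    if matrix.n_genes < n_bins:
        raise ValueError(f"need at least {n_bins} genes for {n_bins} bins")
    means = matrix.tpm.mean(axis=1)
    order = means.reset_index()
    order.columns = ["gene_id", "mean"]
    order = order.sort_values(["mean", "gene_id"], kind="mergesort")
    labels = (BIN_LABELS_3 if n_bins == 3
              else [f"bin_{i + 1}" for i in range(n_bins)])
    assignment = pd.Series(index=means.index, dtype=object)
    for label, chunk in zip(labels, np.array_split(order["gene_id"].to_numpy(),
                                                   n_bins)):
        assignment[chunk] = label
    assignment.name = "abundance_bin"
    return assignment


def cv_percent(values) -> float:
    """Percent coefficient of variation: 100 * sd / mean (sample sd, n-1)."""
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    if mean == 0:
        warnings.warn("CV undefined for zero mean; returning NaN", stacklevel=2)
        return float("nan")
    if len(x) < 2:
        return 0.0
    return float(100.0 * x.std(ddof=1) / mean)


def prevalence_by_bin(gene_sets: dict[str, set], bins: pd.Series) -> pd.DataFrame:
    """Percent of each gene set falling in each abundance bin.

    Rows sum to 100 for non-empty sets; empty sets yield NaN rows. Genes
    outside the bin universe are rejected.
    """
    labels = list(dict.fromkeys(bins))
    universe = set(bins.index)
    rows = {}
    for name, genes in gene_sets.items():
        genes = set(genes)
        stray = genes - universe
        if stray:
            raise ValueError(
                f"set {name!r} has genes outside the universe: {sorted(stray)[:5]}"
            )
        if not genes:
            warnings.warn(f"gene set {name!r} is empty; prevalence undefined",
                          stacklevel=2)
            rows[name] = {lab: float("nan") for lab in labels}
            continue
        members = bins[list(genes)]
        rows[name] = {lab: 100.0 * (members == lab).sum() / len(genes)
                      for lab in labels}
    return pd.DataFrame(rows).T[labels]
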