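"""Differential Shannon Diversity (DSD): per-gene entropy contribution
compared between groups.

For one sample (library), each gene's proportion is

    p_i = TPM_i / sum_j TPM_j

and the library's diversity is the log2 Shannon entropy

    H = -sum_{p_i > 0} p_i log2 p_i        (bits; 0 <= H <= log2 G)

where G is the number of expressed (nonzero) genes. A gene's *percentage
Shannon entropy* (PSE) is its fractional contribution to that entropy,

    PSE_i = (-p_i log2 p_i) / H,

so PSE is 0 for an unexpressed gene, sums to 1 per sample, and approaches
1 when a single gene dominates. DSD for a case/control contrast is the
log2 fold-change of group-mean PSE; the companion DEG statistic is the
log2 fold-change of group-mean TPM. Both arms are tested per gene with a
two-sided Wilcoxon rank-sum (Mann-Whitney) test — on PSE for DSD, on TPM
for DEG — so that the two metrics are directly comparable.

Because PSE depends only on proportions, DSD responds to shifts in a
gene's *share* of the transcriptome even when absolute levels are flat,
and stays at zero when every gene scales together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .compare import call_significant
from .io import ExpressionMatrix, GroupDesign, ensure_tpm

P_SUM_TOL = 1e-6


def gene_proportions(tpm_column) -> np.ndarray:
    """Per-gene proportion p_i = TPM_i / sum TPM over all genes of the sample."""
    x = np.asarray(tpm_column, dtype=float)
    if (x < 0).any():
        raise ValueError("TPM values must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample: proportions undefined")
    return x / total


def shannon_entropy_log2(p) -> float:
    """Log2 Shannon entropy H of a proportion vector, in bits."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > P_SUM_TOL:
        raise ValueError(f"proportions must sum to 1 (got {p.sum():.8g})")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() + 0.0)


def pse(p) -> np.ndarray:
    """Percentage Shannon entropy per gene: (-p_i log2 p_i) / H.

    Requires at least two expressed genes (H > 0); zeros stay zero.
    """
    p = np.asarray(p, dtype=float)
    H = shannon_entropy_log2(p)
    if H == 0.0:
        raise ValueError("PSE undefined: single-gene library has H = 0")
    h = np.zeros_like(p)
    nz = p > 0
    h[nz] = -p[nz] * np.log2(p[nz])
    return h / H


@dataclass
class GeneEntropyTable:
    """Per-(gene, sample) proportion/entropy tables and per-sample summaries."""

    p: pd.DataFrame            # gene x sample proportions
    h: pd.DataFrame            # gene x sample entropy terms -p log2 p (bits)
    pse: pd.DataFrame          # gene x sample PSE (columns sum to 1)
    H: pd.Series               # per-sample total entropy (bits)
    G: pd.Series               # per-sample number of expressed genes


def entropy_table(matrix: ExpressionMatrix) -> GeneEntropyTable:
    """Compute p, entropy terms, PSE, H and G for every sample."""
    matrix = ensure_tpm(matrix)
    tpm = matrix.tpm
    p_cols, h_cols, pse_cols, H_vals, G_vals = {}, {}, {}, {}, {}
    for sample in tpm.columns:
        p = gene_proportions(tpm[sample].to_numpy())
        h = np.zeros_like(p)
        nz = p > 0
        h[nz] = -p[nz] * np.log2(p[nz])
        H = float(h.sum())
        if H == 0.0:
            raise ValueError(
                f"sample {sample!r} expresses a single gene; PSE undefined"
            )
        p_cols[sample], h_cols[sample], pse_cols[sample] = p, h, h / H
        H_vals[sample], G_vals[sample] = H, int(nz.sum())
    idx = tpm.index
    return GeneEntropyTable(
        p=pd.DataFrame(p_cols, index=idx),
        h=pd.DataFrame(h_cols, index=idx),
        pse=pd.DataFrame(pse_cols, index=idx),
        H=pd.Series(H_vals),
        G=pd.Series(G_vals),
    )


def group_mean_pse(table: GeneEntropyTable, design: GroupDesign) -> pd.DataFrame:
    """Per-gene arithmetic mean PSE within each group (genes x groups)."""
    missing = set(table.pse.columns) - set(design.assignments.index)
    if missing:
        raise ValueError(f"samples without group label: {sorted(missing)[:5]}")
    out = {}
    for g in design.groups:
        samples = [s for s in design.samples_in(g) if s in table.pse.columns]
        if samples:
            out[g] = table.pse[samples].mean(axis=1)
    return pd.DataFrame(out)


def _resolve_epsilon(values, policy) -> float:
    """Pseudocount for log2 ratios: half the smallest positive value seen."""
    if isinstance(policy, (int, float)):
        if policy <= 0:
            raise ValueError("epsilon must be positive")
        return float(policy)
    if policy != "auto":
        raise ValueError(f"unknown epsilon policy {policy!r}")
    arr = np.asarray(values, dtype=float)
    pos = arr[arr > 0]
    if pos.size == 0:
        raise ValueError("no positive values to derive epsilon from")
    return float(pos.min() / 2.0)


def log2fc_with_epsilon(case_means, control_means, epsilon_policy="auto"):
    """log2((case + eps)/(control + eps)) with zero-denominator flags.

    Returns ``(log2fc, flags)``; flags mark genes absent in one or both
    groups, whose ratios are epsilon-dominated rather than measured.
    """
    case = np.asarray(case_means, dtype=float)
    control = np.asarray(control_means, dtype=float)
    eps = _resolve_epsilon(np.concatenate([case, control]), epsilon_policy)
    fc = np.log2((case + eps) / (control + eps))
    flags = np.where(
        (case == 0) & (control == 0), "absent_in_both",
        np.where(control == 0, "control_absent",
                 np.where(case == 0, "case_absent", "")),
    )
    fc = np.where((case == 0) & (control == 0), 0.0, fc)
    return fc, flags


def dsd_log2fc(mean_pse_case, mean_pse_control, epsilon_policy="auto"):
    """DSD: log2 fold-change of group-mean PSE, case over control."""
    return log2fc_with_epsilon(mean_pse_case, mean_pse_control, epsilon_policy)


def deg_log2fc(matrix: ExpressionMatrix, design: GroupDesign, case: str,
               control: str, epsilon_policy="auto"):
    """DEG: log2 fold-change of group-mean TPM, case over control."""
    matrix = ensure_tpm(matrix)
    case_mean = matrix.tpm[design.samples_in(case)].mean(axis=1)
    control_mean = matrix.tpm[design.samples_in(control)].mean(axis=1)
    fc, flags = log2fc_with_epsilon(case_mean, control_mean, epsilon_policy)
    return pd.Series(fc, index=matrix.tpm.index), flags


EXACT_MAX_N = 8


def wilcoxon_per_gene(values: pd.DataFrame, design: GroupDesign, case: str,
                      control: str) -> pd.Series:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value per gene.

    Exact enumeration when both groups have <= 8 samples and the gene has
    no ties; otherwise the normal approximation with tie and continuity
    corrections. Genes constant across both groups get p = 1.
    """
    case_samples = design.samples_in(case)
    control_samples = design.samples_in(control)
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("each group needs at least two samples")
    x = values[case_samples].to_numpy(dtype=float)
    y = values[control_samples].to_numpy(dtype=float)

    pvals = np.ones(len(values))
    combined = np.concatenate([x, y], axis=1)
    constant = np.all(combined == combined[:, [0]], axis=1)
    active = ~constant

    small = len(case_samples) <= EXACT_MAX_N and len(control_samples) <= EXACT_MAX_N
    if small:
        for i in np.flatnonzero(active):
            row = combined[i]
            method = "exact" if len(np.unique(row)) == len(row) else "asymptotic"
            pvals[i] = scipy.stats.mannwhitneyu(
                x[i], y[i], alternative="two-sided", method=method
            ).pvalue
    elif active.any():
        res = scipy.stats.mannwhitneyu(
            x[active], y[active], alternative="two-sided",
            method="asymptotic", axis=1,
        )
        pvals[active] = res.pvalue
    return pd.Series(np.minimum(pvals, 1.0), index=values.index)


def differential_table(matrix: ExpressionMatrix, design: GroupDesign,
                       case: str, control: str,
                       epsilon_policy="auto",
                       log2fc_cut: float = 1.0,
                       neglog10p_cut: float = 1.3) -> pd.DataFrame:
    """Per-gene DEG and DSD statistics for one case/control contrast.

    Columns: group-mean TPM and PSE, both log2 fold-changes, Wilcoxon
    p-values (on TPM for DEG, on PSE for DSD), BH-adjusted q-values, zero
    flags, and up/down/ns significance calls at the configured thresholds.
    """
    matrix = ensure_tpm(matrix)
    design.check_matrix(matrix)
    table = entropy_table(matrix)
    mean_pse = group_mean_pse(table, design)

    case_tpm = matrix.tpm[design.samples_in(case)].mean(axis=1)
    control_tpm = matrix.tpm[design.samples_in(control)].mean(axis=1)
    deg, deg_flags = log2fc_with_epsilon(case_tpm, control_tpm, epsilon_policy)
    dsd, dsd_flags = dsd_log2fc(mean_pse[case], mean_pse[control], epsilon_policy)

    p_deg = wilcoxon_per_gene(matrix.tpm, design, case, control)
    p_dsd = wilcoxon_per_gene(table.pse, design, case, control)
    q_deg = multipletests(p_deg, method="fdr_bh")[1]
    q_dsd = multipletests(p_dsd, method="fdr_bh")[1]

    df = pd.DataFrame({
        "mean_tpm_case": case_tpm,
        "mean_tpm_control": control_tpm,
        "mean_pse_case": mean_pse[case],
        "mean_pse_control": mean_pse[control],
        "deg": deg,
        "dsd": dsd,
        "p_deg": p_deg,
        "p_dsd": p_dsd,
        "q_deg": q_deg,
        "q_dsd": q_dsd,
        "flag_deg": deg_flags,
        "flag_dsd": dsd_flags,
    }, index=matrix.tpm.index)
    df["call_deg"] = call_significant(df["deg"], df["p_deg"],
                                      log2fc_cut, neglog10p_cut)
    df["call_dsd"] = call_significant(df["dsd"], df["p_dsd"],
                                      log2fc_cut, neglog10p_cut)
    df.index.name = "gene_id"
    return df
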