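"""Marker-based cell-type composition estimates from bulk expression.

A deliberately transparent reference-based approach: each cell type's
score in a sample is the arithmetic mean TPM of that type's marker genes
found in the matrix, and proportions are scores normalized to sum to
100% per sample. This recovers mixing proportions well when marker sets
are disjoint and strongly cell-type specific, and degrades gracefully
(documented, not hidden) when signatures overlap. No regression or
signature learning is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .compare import percent_change
from .io import ExpressionMatrix, GroupDesign, MarkerReference, ensure_tpm


@dataclass
class DeconvolutionResult:
    """Per-sample cell-type scores/proportions plus marker coverage."""

    scores: pd.DataFrame       # sample x cell_type mean marker TPM
    proportions: pd.DataFrame  # sample x cell_type, rows sum to 100
    coverage: pd.Series        # cell_type -> fraction of markers found


def score_cell_types(matrix: ExpressionMatrix,
                     reference: MarkerReference) -> DeconvolutionResult:
    """Score each cell type as the mean TPM of its markers, normalize to 100%."""
    matrix = ensure_tpm(matrix)
    tpm = matrix.tpm
    present = set(tpm.index)
    scores = {}
    coverage = {}
    for ct in reference.cell_types:
        markers = reference.markers[ct]
        found = [g for g in markers if g in present]
        coverage[ct] = len(found) / len(markers)
        if not found:
            raise ValueError(
                f"cell type {ct!r} has no markers present in the matrix"
            )
        scores[ct] = tpm.loc[found].mean(axis=0)
    scores_df = pd.DataFrame(scores)
    totals = scores_df.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total marker signal: {bad[:5]}")
    proportions = scores_df.div(totals, axis=0) * 100.0
    return DeconvolutionResult(
        scores=scores_df,
        proportions=proportions,
        coverage=pd.Series(coverage, name="marker_coverage"),
    )


def group_composition_stats(result: DeconvolutionResult, design: GroupDesign,
                            control_group: str | None = None) -> pd.DataFrame:
    """Per cell type: group mean +/- SEM, one-way ANOVA across groups, and
    Welch's t-test plus percent change versus the control group."""
    control = control_group or design.control
    props = result.proportions
    missing = set(props.index) - set(design.assignments.index)
    if missing:
        raise ValueError(f"samples without group label: {sorted(missing)[:5]}")
    by_group = {g: props.loc[[s for s in design.samples_in(g)
                              if s in props.index]]
                for g in design.groups}
    for g, df in by_group.items():
        if len(df) < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")

    rows = []
    for ct in props.columns:
        values = {g: by_group[g][ct].to_numpy() for g in design.groups}
        flat = np.concatenate(list(values.values()))
        degenerate = bool(np.allclose(flat, flat[0]))
        if degenerate:
            anova_p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                anova_p = float(scipy.stats.f_oneway(*values.values()).pvalue)
        row = {"cell_type": ct, "anova_p": anova_p, "degenerate": degenerate}
        for g in design.groups:
            v = values[g]
            row[f"mean_{g}"] = float(v.mean())
            row[f"sem_{g}"] = float(v.std(ddof=1) / np.sqrt(len(v)))
        control_mean = row[f"mean_{control}"]
        for g in design.groups:
            if g == control:
                continue
            if degenerate or np.allclose(
                np.concatenate([values[g], values[control]]), values[g][0]
            ):
                welch_p = 1.0
            else:
                welch_p = float(scipy.stats.ttest_ind(
                    values[g], values[control], equal_var=False
                ).pvalue)
            row[f"welch_p_{g}"] = welch_p
            row[f"pct_change_{g}"] = (
                percent_change(control_mean, row[f"mean_{g}"])
                if control_mean > 0 else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_type")
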