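"""Per-sample alpha-diversity indices on integer read counts.

Treats a transcriptome as an ecological community: genes are species and
reads are individuals. The conventions follow the PAST ecology package:
Shannon, equitability (Pielou's J) and evenness use natural logarithms
here; the per-gene entropy machinery in :mod:`txdiv.dsd` uses log base 2.

All indices are computed on raw integer counts, not TPM: Menhinick and
Brillouin are defined on numbers of individuals. Proportion-based indices
(Shannon, J, evenness, dominance) are tolerated on TPM with a warning;
Brillouin refuses non-integer input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import gammaln
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import ExpressionMatrix, GroupDesign

INDEX_NAMES = ["menhinick", "brillouin", "shannon_nat", "equitability_J",
               "evenness", "dominance_D"]


def _as_counts(column) -> np.ndarray:
    x = np.asarray(column, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if x.sum() <= 0:
        raise ValueError("all-zero sample: diversity undefined")
    return x


def _require_integer(x: np.ndarray, index_name: str) -> None:
    if not np.array_equal(x, np.round(x)):
        raise ValueError(
            f"{index_name} is defined on integer read counts only; "
            "got non-integer values (do not pass TPM here)"
        )


def _proportions(x: np.ndarray) -> np.ndarray:
    return x / x.sum()


def menhinick(counts_column) -> float:
    """Menhinick richness: expressed genes over the square root of total reads."""
    x = _as_counts(counts_column)
    _require_integer(x, "Menhinick")
    S = int((x > 0).sum())
    N = x.sum()
    return S / np.sqrt(N)


def brillouin(counts_column) -> float:
    """Brillouin index (ln N! - sum ln n_i!)/N, via log-gamma for stability."""
    x = _as_counts(counts_column)
    _require_integer(x, "Brillouin")
    N = x.sum()
    return float((gammaln(N + 1) - gammaln(x + 1).sum()) / N)


def shannon_nat(counts_column) -> float:
    """Shannon entropy in nats, -sum p ln p over expressed genes."""
    x = _as_counts(counts_column)
    p = _proportions(x)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def equitability_J(counts_column) -> float:
    """Pielou's equitability J = H_nat / ln S; NaN (with warning) when S = 1."""
    x = _as_counts(counts_column)
    S = int((x > 0).sum())
    if S == 1:
        warnings.warn("equitability undefined for a single expressed gene (ln S = 0)",
                      stacklevel=2)
        return float("nan")
    return shannon_nat(x) / np.log(S)


def evenness(counts_column) -> float:
    """Buzas–Gibson evenness e^{H_nat}/S; 1 iff perfectly uniform."""
    x = _as_counts(counts_column)
    S = int((x > 0).sum())
    return float(np.exp(shannon_nat(x)) / S)


def dominance_D(counts_column) -> float:
    """Simpson dominance D = sum p_i^2 (1 - Simpson diversity)."""
    x = _as_counts(counts_column)
    p = _proportions(x)
    return float((p ** 2).sum())


def profile_all(matrix: ExpressionMatrix, design: GroupDesign | None = None,
                use_tpm: bool = False) -> pd.DataFrame:
    """One row per sample: richness S, total reads N, the six indices, group.

    With ``use_tpm=True`` the proportion-based indices are computed on TPM
    (warned), and Menhinick/Brillouin are NaN because they require integer
    read counts.
    """
    if use_tpm or matrix.counts is None:
        if matrix.tpm is None:
            raise ValueError("matrix has neither counts nor TPM")
        warnings.warn(
            "computing proportion-based indices on TPM; Menhinick and "
            "Brillouin require integer counts and are reported as NaN",
            stacklevel=2,
        )
        data, integer_ok = matrix.tpm, False
    else:
        data, integer_ok = matrix.counts, True

    if design is not None:
        design.check_matrix(matrix)

    rows = []
    for sample in data.columns:
        x = data[sample].to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row = {
                    "sample_id": sample,
                    "S": int((x > 0).sum()),
                    "N": float(x.sum()),
                    "menhinick": menhinick(x) if integer_ok else float("nan"),
                    "brillouin": brillouin(x) if integer_ok else float("nan"),
                    "shannon_nat": shannon_nat(x),
                    "equitability_J": equitability_J(x),
                    "evenness": evenness(x),
                    "dominance_D": dominance_D(x),
                }
        except ValueError as exc:
            raise ValueError(f"sample {sample!r}: {exc}") from exc
        if design is not None:
            row["group"] = design.assignments[sample]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    if design is not None:
        cols = ["group"] + [c for c in df.columns if c != "group"]
        df = df[cols]
    return df


@dataclass
class GroupTestResult:
    """One-way ANOVA across groups plus Tukey HSD pairwise table."""

    index_name: str
    F: float
    p: float
    tukey: pd.DataFrame
    degenerate: bool = False


def group_test(profiles: pd.DataFrame, index_name: str,
               alpha: float = 0.05, posthoc: bool = True) -> GroupTestResult:
    """One-way ANOVA with Tukey's post hoc test on one diversity index.

    ``posthoc=False`` skips the Tukey table (empty frame), useful when
    only the omnibus test is needed, e.g. in large simulation sweeps.
    """
    if "group" not in profiles.columns:
        raise ValueError("profiles must carry a 'group' column (pass a design)")
    if index_name not in profiles.columns:
        raise ValueError(f"unknown index {index_name!r}")
    groups = profiles["group"].unique().tolist()
    if len(groups) < 2:
        raise ValueError("group_test needs at least two groups")
    values = [profiles.loc[profiles["group"] == g, index_name].to_numpy()
              for g in groups]
    if any(len(v) < 2 for v in values):
        raise ValueError("every group needs at least two samples")

    flat = np.concatenate(values)
    degenerate = False
    if np.allclose(flat, flat[0]):
        F, p = 0.0, 1.0
        degenerate = True
    elif all(np.allclose(v, v[0]) for v in values):
        # zero within-group variance but different means
        F, p = float("inf"), 0.0
        degenerate = True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = scipy.stats.f_oneway(*values)
        F, p = float(F), float(p)

    if not posthoc:
        tukey_df = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p-adj", "reject"])
    elif degenerate:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
        tukey_df = pd.DataFrame({
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": [np.mean(values[groups.index(b)]) -
                         np.mean(values[groups.index(a)]) for a, b in pairs],
            "p-adj": [p] * len(pairs),
            "reject": [p < alpha] * len(pairs),
        })
    else:
        res = pairwise_tukeyhsd(flat, profiles["group"].to_numpy(), alpha=alpha)
        tukey_df = pd.DataFrame(res.summary().data[1:],
                                columns=res.summary().data[0])
    return GroupTestResult(index_name=index_name, F=F, p=p, tukey=tukey_df,
                           degenerate=degenerate)
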