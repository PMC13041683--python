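"""Expression-matrix data model and plain-text I/O.

The package operates on gene x sample tables of bulk RNA-seq abundance:
raw integer read counts and/or TPM (transcripts per million, per-sample
column sums of 1e6). Genes are rows, samples are columns, in every file
dialect. Gene identifiers are opaque strings; no symbol mapping is done.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

TPM_TOTAL = 1_000_000.0
TPM_RTOL = 1e-6


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


def _check_nonnegative(df: pd.DataFrame, what: str) -> None:
    arr = df.to_numpy()
    if not np.isfinite(arr).all():
        raise ValidationError(f"{what} contains non-finite values")
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"negative {what} value {arr[g, s]} at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample expression table.

    At least one of ``counts`` (non-negative integers) or ``tpm``
    (non-negative reals summing to 1e6 per sample) must be present.
    ``gene_lengths`` (bases) is required only to derive TPM from counts.
    """

    counts: pd.DataFrame | None = None
    tpm: pd.DataFrame | None = None
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts is None and self.tpm is None:
            raise ValidationError("at least one of counts/tpm must be provided")
        for df, what in ((self.counts, "counts"), (self.tpm, "TPM")):
            if df is None:
                continue
            _check_unique(df.index, "gene_ids")
            _check_unique(df.columns, "sample_ids")
            _check_nonnegative(df, what)
        if self.counts is not None and self.tpm is not None:
            if not self.counts.index.equals(self.tpm.index) or not (
                self.counts.columns.equals(self.tpm.columns)
            ):
                raise ValidationError("counts and tpm must share gene/sample ids")
        if self.counts is not None:
            arr = self.counts.to_numpy()
            if not np.array_equal(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
        if self.tpm is not None:
            sums = self.tpm.sum(axis=0)
            bad = ~np.isclose(sums, TPM_TOTAL, rtol=TPM_RTOL)
            if bad.any():
                raise ValidationError(
                    "TPM columns must sum to 1e6 (rel tol 1e-6); offending "
                    f"samples: {list(sums.index[bad][:5])}"
                )
        if self.gene_lengths is not None:
            ref = self.counts if self.counts is not None else self.tpm
            if not self.gene_lengths.index.equals(ref.index):
                raise ValidationError("gene_lengths index must match gene_ids")
            if (self.gene_lengths <= 0).any():
                raise ValidationError("gene lengths must be positive")

    @property
    def gene_ids(self) -> list[str]:
        df = self.counts if self.counts is not None else self.tpm
        return list(df.index)

    @property
    def sample_ids(self) -> list[str]:
        df = self.counts if self.counts is not None else self.tpm
        return list(df.columns)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class GroupDesign:
    """Sample-to-group assignment with a designated control group."""

    assignments: pd.Series  # sample_id -> group label
    groups: list[str] = field(default_factory=list)  # ordered
    control: str | None = None

    def __post_init__(self) -> None:
        self.assignments = pd.Series(self.assignments, dtype=object)
        _check_unique(self.assignments.index, "sample_ids in design")
        seen = list(dict.fromkeys(self.assignments))
        if not self.groups:
            self.groups = seen
        else:
            missing = set(seen) - set(self.groups)
            if missing:
                raise ValidationError(f"groups missing from order: {sorted(missing)}")
        if self.control is None:
            self.control = self.groups[0]
        elif self.control not in self.groups:
            raise ValidationError(f"control group {self.control!r} not in design")

    def samples_in(self, group: str) -> list[str]:
        if group not in self.groups:
            raise ValidationError(f"unknown group {group!r}")
        return list(self.assignments.index[self.assignments == group])

    def check_matrix(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must carry exactly one group label."""
        missing = set(matrix.sample_ids) - set(self.assignments.index)
        if missing:
            raise ValidationError(f"samples without group label: {sorted(missing)[:5]}")

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in self.groups}


@dataclass
class MarkerReference:
    """Cell-type -> marker-gene lists for reference-based deconvolution."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        _check_unique(list(self.markers), "cell types")
        for ct, genes in self.markers.items():
            if not genes:
                raise ValidationError(f"cell type {ct!r} has an empty marker list")
            _check_unique(genes, f"markers of {ct!r}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.markers)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValidationError(f"empty cell in row {row!r} of {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric value in {path}: {exc}") from exc
    df.index.name = None
    df.columns.name = None
    return df


def read_expression_tsv(path, value_kind: str, rescale: bool = False) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene IDs, header sample IDs).

    ``value_kind`` is ``"counts"`` or ``"tpm"``. With ``rescale=True`` a TPM
    table stored as relative shares is rescaled so columns sum to 1e6.
    """
    df = _read_table(path)
    if value_kind == "counts":
        return ExpressionMatrix(counts=df)
    if value_kind == "tpm":
        if rescale:
            sums = df.sum(axis=0)
            if (sums <= 0).any():
                raise ValidationError("cannot rescale an all-zero sample column")
            df = df * (TPM_TOTAL / sums)
        return ExpressionMatrix(tpm=df)
    raise ValueError(f"value_kind must be 'counts' or 'tpm', got {value_kind!r}")


def write_expression_tsv(matrix: ExpressionMatrix, path, value_kind: str,
                         header_lines: list[str] | None = None) -> None:
    df = matrix.counts if value_kind == "counts" else matrix.tpm
    if df is None:
        raise ValueError(f"matrix has no {value_kind} slot")
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.rename_axis("gene_id").to_csv(fh, sep="\t")


def _read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression_mtx(matrix_path, genes_path, samples_path,
                        value_kind: str) -> ExpressionMatrix:
    """Read a Matrix Market coordinate file plus gene/sample ID sidecars."""
    m = scipy.io.mmread(matrix_path)
    genes = _read_id_list(genes_path)
    samples = _read_id_list(samples_path)
    if m.shape != (len(genes), len(samples)):
        raise ValidationError(
            f"MTX header {m.shape} does not match ID lists "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    dense = np.asarray(m.todense() if scipy.sparse.issparse(m) else m, dtype=float)
    df = pd.DataFrame(dense, index=genes, columns=samples)
    if value_kind == "counts":
        return ExpressionMatrix(counts=df)
    return ExpressionMatrix(tpm=df)


def write_expression_mtx(matrix: ExpressionMatrix, matrix_path, genes_path,
                         samples_path, value_kind: str) -> None:
    df = matrix.counts if value_kind == "counts" else matrix.tpm
    if df is None:
        raise ValueError(f"matrix has no {value_kind} slot")
    scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(df.to_numpy()))
    for path, ids in ((genes_path, df.index), (samples_path, df.columns)):
        with open(path, "w") as fh:
            fh.write("\n".join(map(str, ids)) + "\n")


def read_design_tsv(path, control: str | None = None) -> GroupDesign:
    """Read a two-column ``sample_id<TAB>group`` design table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ValidationError(
            f"design table must have columns sample_id, group; got {list(df.columns)}"
        )
    return GroupDesign(
        assignments=pd.Series(df["group"].values, index=df["sample_id"].values),
        control=control,
    )


def write_design_tsv(design: GroupDesign, path) -> None:
    pd.DataFrame({
        "sample_id": design.assignments.index,
        "group": design.assignments.values,
    }).to_csv(path, sep="\t", index=False)


def read_marker_tsv(path) -> MarkerReference:
    """Read a two-column ``cell_type<TAB>gene_id`` marker reference."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["cell_type", "gene_id"]:
        raise ValidationError(
            f"marker table must have columns cell_type, gene_id; got {list(df.columns)}"
        )
    markers: dict[str, list[str]] = {}
    for ct, gid in zip(df["cell_type"], df["gene_id"]):
        markers.setdefault(ct, []).append(gid)
    return MarkerReference(markers=markers)


def write_marker_tsv(reference: MarkerReference, path) -> None:
    rows = [(ct, g) for ct, genes in reference.markers.items() for g in genes]
    pd.DataFrame(rows, columns=["cell_type", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# TPM derivation
# ---------------------------------------------------------------------------

def tpm_from_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Derive TPM from counts and gene lengths.

    TPM_i = 1e6 * (count_i / length_i) / sum_j (count_j / length_j),
    so per-sample columns sum to 1e6 and a zero-count gene has TPM 0.
    """
    if matrix.counts is None:
        raise ValidationError("tpm_from_counts requires a counts slot")
    if matrix.gene_lengths is None:
        raise ValidationError("tpm_from_counts requires gene_lengths")
    rates = matrix.counts.div(matrix.gene_lengths, axis=0)
    totals = rates.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValidationError(f"all-zero sample columns (TPM undefined): {bad[:5]}")
    tpm = rates * (TPM_TOTAL / totals)
    return ExpressionMatrix(counts=matrix.counts, tpm=tpm,
                            gene_lengths=matrix.gene_lengths)


def ensure_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return a matrix with the TPM slot filled, deriving it if needed."""
    if matrix.tpm is not None:
        return matrix
    if matrix.gene_lengths is None and matrix.counts is not None:
        warnings.warn(
            "no gene lengths given; deriving TPM assuming equal lengths",
            stacklevel=2,
        )
        m = ExpressionMatrix(
            counts=matrix.counts,
            gene_lengths=pd.Series(1000.0, index=matrix.counts.index),
        )
        return tpm_from_counts(m)
    return tpm_from_counts(matrix)
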