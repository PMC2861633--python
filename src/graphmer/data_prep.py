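"""Expression-matrix and promoter preparation.

Loads a gene x sample expression table, averages replicate columns into
timepoints, removes baseline / low-variance genes, and standardizes columns
for the regression model.  Promoters are read from FASTA and anchored at the
transcription start site (TSS): the last base of each record is the base
immediately upstream of the TSS, and upstream distance increases toward the
5' end of the record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


@dataclass
class ExpressionMatrix:
    """Gene x timepoint matrix of (log-scale) expression values."""

    gene_ids: list[str]
    values: np.ndarray
    column_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("row count does not match number of gene ids")
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("column count does not match number of labels")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            values=frame.to_numpy(dtype=float),
            column_labels=[str(c) for c in frame.columns],
        )

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.values[rows], list(self.column_labels))


@dataclass
class PromoterSet:
    """TSS-anchored promoter sequences, one per gene.

    Position 1 is the base immediately upstream of the TSS (the last character
    of the stored sequence); positions increase upstream.
    """

    gene_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.sequences):
            raise ValueError("gene_ids and sequences must be parallel lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in promoter set")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def mapping(self) -> dict[str, str]:
        return dict(zip(self.gene_ids, self.sequences))

    def subset(self, gene_ids: Sequence[str]) -> "PromoterSet":
        m = self.mapping
        return PromoterSet(list(gene_ids), [m[g] for g in gene_ids])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for g, s in zip(self.gene_ids, self.sequences):
                fh.write(f">{g}\n{s}\n")


@dataclass
class StandardizationStats:
    """Per-column mean/sd learned on training data (population sd)."""

    means: np.ndarray
    sds: np.ndarray
    degenerate: np.ndarray  # boolean mask of zero-variance columns


@dataclass
class FilterReport:
    n_input: int
    n_baseline_removed: int
    n_lowvar_removed: int
    n_kept: int
    q_low_value: float
    q_high_value: float


def average_replicates(
    raw: pd.DataFrame,
    replicate_map: Mapping[str, str],
    on_all_missing: str = "raise",
) -> ExpressionMatrix:
    """Average replicate columns of ``raw`` into one column per timepoint.

    ``replicate_map`` maps each sample (column) label to its timepoint label.
    Missing entries (NaN) are ignored in the mean; a cell whose replicates are
    all missing raises by default, or drops the gene with
    ``on_all_missing="drop"``.
    """
    if raw.size == 0:
        raise ValueError("empty expression matrix")
    unmapped = [c for c in raw.columns if c not in replicate_map]
    if unmapped:
        raise KeyError(f"samples not present in replicate map: {unmapped}")
    if on_all_missing not in ("raise", "drop"):
        raise ValueError("on_all_missing must be 'raise' or 'drop'")

    # timepoint order: first appearance over the sample columns
    timepoints: list[str] = []
    for c in raw.columns:
        tp = replicate_map[c]
        if tp not in timepoints:
            timepoints.append(tp)

    cols = []
    for tp in timepoints:
        members = [c for c in raw.columns if replicate_map[c] == tp]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled below
            cols.append(np.nanmean(raw[members].to_numpy(dtype=float), axis=1))
    values = np.column_stack(cols)

    all_missing = np.isnan(values).any(axis=1)
    if all_missing.any():
        bad = [str(raw.index[i]) for i in np.flatnonzero(all_missing)]
        if on_all_missing == "raise":
            raise ValueError(f"all replicates missing for genes: {bad[:10]}")
        warnings.warn(f"dropping {len(bad)} genes with an all-missing timepoint")
        keep = ~all_missing
        values = values[keep]
        genes = [str(g) for g, k in zip(raw.index, keep) if k]
    else:
        genes = [str(g) for g in raw.index]
    return ExpressionMatrix(genes, values, timepoints)


def filter_genes(
    expr: ExpressionMatrix,
    q_low: float = 0.05,
    q_high: float = 0.95,
    var_min: float = 0.1,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop baseline and low-variance genes.

    Quantiles are pooled over *all* values of the matrix.  A gene is removed if
    every one of its values lies strictly inside the (q_low, q_high) quantile
    interval (baseline expression), or if its row variance (population) is
    below ``var_min``.
    """
    if not (0 <= q_low < q_high <= 1):
        raise ValueError("require 0 <= q_low < q_high <= 1")
    values = expr.values
    lo = float(np.quantile(values, q_low))
    hi = float(np.quantile(values, q_high))
    if q_low == 0 and q_high == 1:
        # degenerate interval spans the whole data range: nothing is baseline
        baseline = np.zeros(values.shape[0], dtype=bool)
    else:
        baseline = np.all((values > lo) & (values < hi), axis=1)
    lowvar = values.var(axis=1) < var_min
    keep = ~(baseline | lowvar)
    report = FilterReport(
        n_input=expr.n_genes,
        n_baseline_removed=int(baseline.sum()),
        n_lowvar_removed=int(lowvar.sum()),
        n_kept=int(keep.sum()),
        q_low_value=lo,
        q_high_value=hi,
    )
    if not keep.any():
        warnings.warn("all genes removed by expression filters")
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(genes, values[keep], list(expr.column_labels)), report


def standardize(
    matrix: np.ndarray,
    stats: StandardizationStats | None = None,
) -> tuple[np.ndarray, StandardizationStats]:
    """Column-standardize to zero mean / unit variance (population sd).

    If ``stats`` is supplied (e.g. training statistics applied to test data),
    those means/sds are used instead of recomputing.  Zero-variance columns are
    mapped to all-zero and flagged in the returned stats.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if stats is None:
        if matrix.shape[0] < 2:
            raise ValueError("need at least two rows to standardize")
        means = matrix.mean(axis=0)
        sds = matrix.std(axis=0)  # population sd (ddof=0)
        degenerate = sds == 0
        stats = StandardizationStats(means, sds, degenerate)
    safe_sds = np.where(stats.degenerate, 1.0, stats.sds)
    out = (matrix - stats.means) / safe_sds
    out[:, stats.degenerate] = 0.0
    return out, stats


def load_promoters(path, max_len: int = 500) -> PromoterSet:
    """Read promoters from FASTA, keeping the ``max_len`` bases nearest the TSS.

    The TSS-proximal end is the 3' end of each upstream record, so truncation
    keeps the record suffix.  Sequences shorter than ``max_len`` are kept as-is
    (genes with short upstream intergenic regions).
    """
    gene_ids: list[str] = []
    sequences: list[str] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        gid = record.id
        if gid in seen:
            raise ValueError(f"duplicate promoter id: {gid}")
        seq = str(record.seq).upper()
        if not seq:
            warnings.warn(f"skipping empty promoter record {gid}")
            continue
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"invalid characters {sorted(bad)} in promoter {gid}")
        seen.add(gid)
        gene_ids.append(gid)
        sequences.append(seq[-max_len:] if max_len else seq)
    return PromoterSet(gene_ids, sequences)


def load_expression_tsv(path) -> pd.DataFrame:
    """Read a gene x sample TSV (first column gene id, header = sample labels)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def load_replicate_map(path) -> dict[str, str]:
    """Read a two-column sample<TAB>timepoint map."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("replicate map needs two tab-separated columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def load_gene_set(path) -> list[str]:
    """Read a one-gene-per-line set file ('#' comments ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def align_genes(
    expr: ExpressionMatrix, promoters: PromoterSet
) -> tuple[ExpressionMatrix, PromoterSet]:
    """Restrict both inputs to their common genes, in expression order."""
    have = set(promoters.gene_ids)
    common = [g for g in expr.gene_ids if g in have]
    if not common:
        raise ValueError("no genes shared between expression matrix and promoters")
    return expr.subset(common), promoters.subset(common)
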