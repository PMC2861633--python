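"""Assigning genes to latent factors.

A gene's affinity for factor i combines how well the input-side latent score
captures its k-mer profile (T[g, i]) and how similar the output-side latent
score is to its expression profile (U[g, i]).  The default gene-factor score
is the product T[g, i] * U[g, i], which is invariant under the joint
(w_i, c_i) sign flip.  A gene is assigned to its best-scoring factor only
when that score lands in the top fraction of all best scores (pooled over
genes), and genes whose best factor is the last one retained are set aside
from downstream motif gene lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_pls import PlsModel
from .kmer_features import KmerMatrix


@dataclass
class FactorAssignment:
    """Per-gene best factor, score and assignment flag."""

    gene_ids: list[str]
    best_factor: np.ndarray  # 0-based factor index
    best_score: np.ndarray
    assigned: np.ndarray  # bool
    n_factors: int
    top_frac: float
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "factor": self.best_factor + 1,  # 1-based in the report
                "score": self.best_score,
                "assigned": self.assigned,
            }
        )

    def genes_for_factor(self, i: int) -> list[str]:
        """Assigned genes of 0-based factor i (the last factor acts as a sink
        for residual structure and is excluded from motif gene lists)."""
        if not (0 <= i < self.n_factors):
            raise IndexError(f"factor {i} out of range")
        mask = self.assigned & (self.best_factor == i)
        return [g for g, m in zip(self.gene_ids, mask) if m]


def factor_scores(model: PlsModel, n_factors: int | None = None, method: str = "product") -> np.ndarray:
    """Gene x factor score matrix from the latent score matrices T and U."""
    K = model.n_factors if n_factors is None else int(n_factors)
    if not (1 <= K <= model.n_factors):
        raise ValueError(f"n_factors must be in 1..{model.n_factors}")
    T = model.T[:, :K]
    U = model.U[:, :K]
    if method == "product":
        return T * U
    if method == "min":
        return np.minimum(T, U)
    raise ValueError(f"unknown score method {method!r}")


def factor_score(model: PlsModel, g: int, i: int, method: str = "product") -> float:
    """Score of gene g (row index) for 0-based factor i."""
    if not (0 <= i < model.n_factors):
        raise IndexError(f"factor {i} out of range")
    return float(factor_scores(model, method=method)[g, i])


def assign_genes(
    model: PlsModel,
    gene_ids: list[str],
    n_factors: int = 5,
    top_frac: float = 0.2,
    method: str = "product",
) -> FactorAssignment:
    """Assign each gene to its best factor when the score is a pooled top hit.

    The threshold is the (1 - top_frac) quantile of the per-gene best scores
    (pooled across factors, not per factor).
    """
    if not (0 < top_frac <= 1):
        raise ValueError("top_frac must be in (0, 1]")
    n_factors = min(n_factors, model.n_factors)
    S = factor_scores(model, n_factors=n_factors, method=method)
    best = S.argmax(axis=1)
    best_score = S[np.arange(S.shape[0]), best]
    threshold = float(np.quantile(best_score, 1.0 - top_frac))
    assigned = best_score >= threshold
    return FactorAssignment(
        list(gene_ids), best, best_score, assigned, n_factors, top_frac, threshold
    )


def motif_gene_ranking(
    assignment: FactorAssignment,
    factor: int,
    motif_kmers: list[str],
    km: KmerMatrix,
) -> pd.DataFrame:
    """Rank a factor's assigned genes by total counts of the motif's k-mers.

    Count ties break by the gene's factor score, descending.
    """
    genes = assignment.genes_for_factor(factor)
    if not genes:
        raise ValueError(f"factor {factor} has no assigned genes")
    present = [s for s in motif_kmers if s in set(km.kmers)]
    if not present:
        raise ValueError("none of the motif's k-mers are in the count matrix")
    sub = km.select(present)
    row_of = {g: i for i, g in enumerate(km.gene_ids)}
    counts = np.asarray(sub.counts.sum(axis=1)).ravel()
    score_of = dict(zip(assignment.gene_ids, assignment.best_score))
    frame = pd.DataFrame(
        {
            "gene": genes,
            "count": [int(counts[row_of[g]]) for g in genes],
            "score": [score_of[g] for g in genes],
        }
    )
    return frame.sort_values(
        ["count", "score"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)


def correlation_geneset(
    Y: np.ndarray, gene_ids: list[str], c: np.ndarray, r_min: float
) -> list[str]:
    """Genes whose expression row correlates with trajectory c above r_min."""
    if not (-1 <= r_min <= 1):
        raise ValueError("r_min must be in [-1, 1]")
    Y = np.asarray(Y, dtype=float)
    c = np.asarray(c, dtype=float)
    out = []
    c0 = c - c.mean()
    nc = np.linalg.norm(c0)
    if nc == 0:
        raise ValueError("constant trajectory c")
    skipped = 0
    for g, row in zip(gene_ids, Y):
        r0 = row - row.mean()
        nr = np.linalg.norm(r0)
        if nr == 0:
            skipped += 1
            continue
        if float(r0 @ c0) / (nr * nc) > r_min:
            out.append(g)
    if skipped:
        warnings.warn(f"skipped {skipped} constant expression rows")
    return out
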