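"""Cross-validation over the number of latent factors, and controls.

Implements 10-fold cross-validation of (graph-regularized) SIMPLS with NMSE
truncated to every K in 0..K_max, the randomized sequence/expression pairing
negative control, and per-gene-set NMSE profiles with per-factor loss
reductions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import graph_pls
from .data_prep import standardize
from .graph_pls import PlsModel, nmse, regress_latent


@dataclass
class CvResult:
    """Per-K cross-validated NMSE (mean/sd over folds)."""

    k_grid: np.ndarray
    fold_nmse: np.ndarray  # n_folds x len(k_grid)
    mean_nmse: np.ndarray
    sd_nmse: np.ndarray
    chosen_k: int
    seed: int
    fold_assignments: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"K": self.k_grid, "mean_nmse": self.mean_nmse, "sd_nmse": self.sd_nmse}
        )


def fold_assignments(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded fold labels in 0..n_folds-1; depends only on (seed, n, n_folds)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        labels[chunk] = f
    return labels


def _fit(method: str, X, Y, K, **kwargs) -> PlsModel:
    if method == "simpls":
        kwargs.pop("graph", None)
        kwargs.pop("laplacian", None)
        kwargs.pop("lambda_lasso", None)
        kwargs.pop("lambda_graph", None)
        return graph_pls.fit_simpls(X, Y, K)
    if method == "graph":
        return graph_pls.fit_graph_pls(X, Y, K, **kwargs)
    raise ValueError(f"unknown method {method!r}")


def truncated_nmse(
    model: PlsModel,
    Y_train_std: np.ndarray,
    X_test_std: np.ndarray,
    Y_test_std: np.ndarray,
    k_grid: Sequence[int],
) -> np.ndarray:
    """Held-out NMSE using only the first K factors, for each K in k_grid.

    K = 0 is the test-mean predictor and scores exactly 1 by the NMSE
    normalization.
    """
    out = np.empty(len(k_grid))
    for idx, K in enumerate(k_grid):
        K = int(K)
        if K == 0:
            out[idx] = 1.0
            continue
        Keff = min(K, model.n_factors)
        B_inner = regress_latent(Y_train_std, model.T[:, :Keff])
        Y_hat = X_test_std @ model.W[:, :Keff] @ B_inner
        out[idx] = nmse(Y_test_std, Y_hat)
    return out


def cross_validate(
    X_raw: np.ndarray,
    Y_raw: np.ndarray,
    method: str = "graph",
    K_max: int = 5,
    n_folds: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> CvResult:
    """K-fold CV: standardize on train, fit K_max factors, score truncations.

    Genes are split into folds by a seeded permutation; each fold serves once
    as the held-out set.  The chosen K is the argmin of the mean NMSE curve
    (smallest K on ties).
    """
    X_raw = np.asarray(X_raw, dtype=float)
    Y_raw = np.asarray(Y_raw, dtype=float)
    n = X_raw.shape[0]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    folds = fold_assignments(n, n_folds, seed)
    k_grid = np.arange(K_max + 1)
    fold_scores = np.empty((n_folds, K_max + 1))
    for f in range(n_folds):
        test = folds == f
        train = ~test
        if test.sum() < 2 or train.sum() < 2:
            raise ValueError(f"fold {f} has too few genes")
        X_tr, x_stats = standardize(X_raw[train])
        Y_tr, y_stats = standardize(Y_raw[train])
        X_te, _ = standardize(X_raw[test], x_stats)
        Y_te, _ = standardize(Y_raw[test], y_stats)
        model = _fit(method, X_tr, Y_tr, K_max, **fit_kwargs)
        fold_scores[f] = truncated_nmse(model, Y_tr, X_te, Y_te, k_grid)
    mean = fold_scores.mean(axis=0)
    sd = fold_scores.std(axis=0, ddof=1)
    chosen = int(k_grid[int(np.argmin(mean))])  # argmin takes the smallest K on ties
    return CvResult(k_grid, fold_scores, mean, sd, chosen, seed, folds, method)


def randomize_pairing(
    X: np.ndarray, Y: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Break the sequence/expression correspondence by permuting rows of Y."""
    X = np.asarray(X)
    Y = np.asarray(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of genes")
    rng = np.random.default_rng(seed)
    return X, Y[rng.permutation(Y.shape[0])]


def geneset_nmse(
    model: PlsModel,
    X_std: np.ndarray,
    Y_std: np.ndarray,
    Y_train_std: np.ndarray,
    gene_mask: np.ndarray,
    k_grid: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-K NMSE restricted to a gene subset, with per-factor loss reduction.

    The subset NMSE uses the subset's own variance as normalizer (K = 0 is
    exactly 1); delta(K) = NMSE(K-1) - NMSE(K) reports how much each factor
    contributes on the subset.
    """
    gene_mask = np.asarray(gene_mask, dtype=bool)
    if not gene_mask.any():
        raise ValueError("empty gene set")
    if k_grid is None:
        k_grid = np.arange(model.n_factors + 1)
    X_sub = np.asarray(X_std)[gene_mask]
    Y_sub = np.asarray(Y_std)[gene_mask]
    # subset normalizer uses the grand mean over the subset's cells so that
    # singleton sets stay well-defined; on standardized data the grand mean
    # is ~0 and the full-set profile coincides with the global NMSE
    denom = float(((Y_sub - Y_sub.mean()) ** 2).sum())
    if denom == 0:
        raise ValueError("constant expression on the gene subset")
    scores = np.empty(len(k_grid))
    for idx, K in enumerate(k_grid):
        K = int(K)
        if K == 0:
            scores[idx] = 1.0
            continue
        Keff = min(K, model.n_factors)
        B_inner = regress_latent(Y_train_std, model.T[:, :Keff])
        Y_hat = X_sub @ model.W[:, :Keff] @ B_inner
        scores[idx] = float(((Y_sub - Y_hat) ** 2).sum()) / denom
    frame = pd.DataFrame({"K": list(k_grid), "nmse": scores})
    frame["delta"] = -frame["nmse"].diff()
    return frame
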