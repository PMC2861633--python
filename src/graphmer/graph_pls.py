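"""SIMPLS and graph-regularized SIMPLS for sequence-to-expression regression.

The model learns K weight vectors w_a over k-mer features whose latent
factors t_a = X w_a have maximal covariance with directions in the expression
matrix Y.  SIMPLS deflates the cross-product matrix S = X'Y rather than X, so
the latent factors come out mutually orthogonal.  The graph-regularized
variant adds, inside each factor's power iteration, (i) a Laplacian-smoothed
linear solve (I + lambda_graph L) w~ = S q that pulls sequence-similar k-mers
toward a common weight, and (ii) soft-thresholding with a scale-free
threshold delta = lambda_lasso * max|w~| that zeroes most coordinates.  With
both penalties at zero the iteration reduces exactly to SIMPLS.

Y is then regressed on the latent factors by OLS (ridge fallback), giving the
final map B from standardized k-mer counts to standardized expression.
Prediction error is reported as NMSE, normalized so that the zero-factor
(test-mean) predictor scores exactly 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .kmer_graph import KmerGraph


@dataclass
class PlsModel:
    """Fitted (graph-regularized) SIMPLS model.

    Columns of W/T/C/U/P correspond to latent factors; ||w_a|| = 1 and the
    sign gauge is fixed so the largest-magnitude entry of each c_a is
    positive.
    """

    W: np.ndarray  # p x K motif weight vectors
    T: np.ndarray  # n x K input latent factors, t = X w
    C: np.ndarray  # q x K expression weight vectors (unit norm)
    U: np.ndarray  # n x K output latent scores, u = Y c
    P: np.ndarray  # p x K loadings
    B_inner: np.ndarray  # K x q regression of Y on T
    B: np.ndarray  # p x q full coefficient matrix, W @ B_inner
    meta: dict = field(default_factory=dict)

    @property
    def n_factors(self) -> int:
        return self.W.shape[1]

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("W", "T", "C", "U", "P", "B_inner", "B"):
            arr = getattr(self, name)
            pd.DataFrame(arr).to_csv(d / f"{name}.tsv", sep="\t", index=False, header=False)
        with open(d / "meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, directory) -> "PlsModel":
        d = Path(directory)
        arrays = {}
        for name in ("W", "T", "C", "U", "P", "B_inner", "B"):
            arrays[name] = pd.read_csv(d / f"{name}.tsv", sep="\t", header=None).to_numpy(
                dtype=float
            )
        with open(d / "meta.json") as fh:
            meta = json.load(fh)
        return cls(**arrays, meta=meta)


def _sign_fix(w, t, c, u):
    """Flip (w, t, c, u) jointly so the largest-|entry| of c is positive."""
    j = int(np.argmax(np.abs(c)))
    if c[j] < 0:
        return -w, -t, -c, -u
    return w, t, c, u


def _finalize_factor(X, Y, w, V_prev):
    """Shared SIMPLS bookkeeping: scores, loadings, deflation direction."""
    t = X @ w
    tt = float(t @ t)
    if tt <= 0:
        return None
    c_raw = Y.T @ t
    norm_c = np.linalg.norm(c_raw)
    if norm_c == 0:
        return None
    c = c_raw / norm_c
    u = Y @ c
    w, t, c, u = _sign_fix(w, t, c, u)
    p_load = X.T @ t / tt
    v = p_load.copy()
    for vp in V_prev:
        v -= vp * (vp @ v)
    nv = np.linalg.norm(v)
    if nv == 0:
        return None
    v /= nv
    return w, t, c, u, p_load, v


def fit_simpls(X: np.ndarray, Y: np.ndarray, K: int) -> PlsModel:
    """Standard SIMPLS on standardized X (n x p) and Y (n x q).

    Each weight vector is the dominant left singular vector of the deflated
    cross-product matrix; deflation projects out the orthonormalized loadings
    so latent factors stay mutually orthogonal.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    S = X.T @ Y
    s_ref = np.linalg.norm(S)
    Ws, Ts, Cs, Us, Ps, Vs = [], [], [], [], [], []
    for _ in range(K):
        U_svd, svals, _ = np.linalg.svd(S, full_matrices=False)
        if s_ref == 0 or svals[0] <= 1e-12 * s_ref:
            warnings.warn(f"cross-covariance exhausted; stopping at {len(Ws)} factors")
            break
        out = _finalize_factor(X, Y, U_svd[:, 0], Vs)
        if out is None:
            warnings.warn(f"degenerate factor; stopping at {len(Ws)} factors")
            break
        w, t, c, u, p_load, v = out
        Ws.append(w); Ts.append(t); Cs.append(c); Us.append(u); Ps.append(p_load); Vs.append(v)
        S = S - np.outer(v, v @ S)
    return _assemble(X, Y, Ws, Ts, Cs, Us, Ps, meta={"method": "simpls", "K": len(Ws)})


def fit_graph_pls(
    X: np.ndarray,
    Y: np.ndarray,
    K: int,
    lambda_lasso: float = 0.1,
    lambda_graph: float = 5.0,
    graph: KmerGraph | None = None,
    laplacian: sp.spmatrix | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> PlsModel:
    """Graph-regularized SIMPLS.

    Per factor, alternate on the deflated cross-product S: starting from the
    dominant right singular vector q, solve (I + lambda_graph L) w~ = S q,
    soft-threshold with delta = lambda_lasso * max|w~| (halving delta if the
    result is identically zero), renormalize w, and update
    q = S'w / ||S'w|| until max|w_new - w_old| < tol.  Deflation and the sign
    gauge are exactly those of :func:`fit_simpls`.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if lambda_lasso < 0 or lambda_graph < 0:
        raise ValueError("penalties must be non-negative")
    p = X.shape[1]

    solve = None
    if lambda_graph > 0:
        if laplacian is None:
            if graph is None:
                raise ValueError("lambda_graph > 0 requires a k-mer graph or Laplacian")
            laplacian = graph.laplacian
        if laplacian.shape != (p, p):
            raise ValueError("Laplacian dimension does not match feature count")
        M = (sp.identity(p, format="csc") + lambda_graph * laplacian.tocsc()).tocsc()
        try:
            lu = spla.splu(M)
        except RuntimeError as exc:  # singular / ill-conditioned factorization
            raise np.linalg.LinAlgError(f"graph-smoothing solve failed: {exc}") from exc
        solve = lu.solve

    S = X.T @ Y
    s_ref = np.linalg.norm(S)
    Ws, Ts, Cs, Us, Ps, Vs = [], [], [], [], [], []
    for _ in range(K):
        U_svd, svals, Vt = np.linalg.svd(S, full_matrices=False)
        if s_ref == 0 or svals[0] <= 1e-12 * s_ref:
            warnings.warn(f"cross-covariance exhausted; stopping at {len(Ws)} factors")
            break
        q = Vt[0]
        w_old = None
        converged = False
        w = U_svd[:, 0]
        for _it in range(max_iter):
            z = S @ q
            w_tilde = solve(z) if solve is not None else z
            scale = float(np.max(np.abs(w_tilde)))
            if scale == 0:
                break
            if lambda_lasso > 0:
                delta = lambda_lasso * scale
                w = _soft_threshold(w_tilde, delta)
                while not np.any(w):
                    delta *= 0.5
                    w = _soft_threshold(w_tilde, delta)
            else:
                w = w_tilde
            w = w / np.linalg.norm(w)
            sq = S.T @ w
            nq = np.linalg.norm(sq)
            if nq == 0:
                break
            if w_old is not None and float(w @ w_old) < 0:
                w = -w
                sq = -sq
            q = sq / nq
            if w_old is not None and float(np.max(np.abs(w - w_old))) < tol:
                converged = True
                break
            w_old = w
        if not converged:
            warnings.warn("inner iteration did not converge; using last iterate")
        out = _finalize_factor(X, Y, w, Vs)
        if out is None:
            warnings.warn(f"degenerate factor; stopping at {len(Ws)} factors")
            break
        w, t, c, u, p_load, v = out
        Ws.append(w); Ts.append(t); Cs.append(c); Us.append(u); Ps.append(p_load); Vs.append(v)
        S = S - np.outer(v, v @ S)
    meta = {
        "method": "graph_pls",
        "K": len(Ws),
        "lambda_lasso": lambda_lasso,
        "lambda_graph": lambda_graph,
        "tol": tol,
        "max_iter": max_iter,
    }
    return _assemble(X, Y, Ws, Ts, Cs, Us, Ps, meta=meta)


def _soft_threshold(x: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - delta, 0.0)


def _assemble(X, Y, Ws, Ts, Cs, Us, Ps, meta) -> PlsModel:
    p, q = X.shape[1], Y.shape[1]
    if not Ws:
        empty = lambda r: np.zeros((r, 0))
        return PlsModel(
            empty(p), empty(X.shape[0]), empty(q), empty(X.shape[0]), empty(p),
            np.zeros((0, q)), np.zeros((p, q)), meta=meta,
        )
    W = np.column_stack(Ws)
    T = np.column_stack(Ts)
    C = np.column_stack(Cs)
    U = np.column_stack(Us)
    P = np.column_stack(Ps)
    B_inner = regress_latent(Y, T)
    B = W @ B_inner
    return PlsModel(W, T, C, U, P, B_inner, B, meta=meta)


def regress_latent(Y: np.ndarray, T: np.ndarray, ridge_eps: float = 0.0) -> np.ndarray:
    """OLS (optionally ridge) coefficients mapping latent factors T to Y.

    Rank-deficient T falls back to a small ridge with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    T = np.asarray(T, dtype=float)
    if T.shape[1] == 0:
        return np.zeros((0, Y.shape[1]))
    if ridge_eps > 0:
        G = T.T @ T + ridge_eps * np.eye(T.shape[1])
        return np.linalg.solve(G, T.T @ Y)
    coef, _, rank, _ = np.linalg.lstsq(T, Y, rcond=None)
    if rank < T.shape[1]:
        warnings.warn("rank-deficient latent factors; ridge fallback")
        return regress_latent(Y, T, ridge_eps=1e-8 * float(np.trace(T.T @ T)) / T.shape[1])
    return coef


def predict(model: PlsModel, X_std: np.ndarray) -> np.ndarray:
    """Predict standardized expression from standardized k-mer counts."""
    X_std = np.asarray(X_std, dtype=float)
    if X_std.shape[1] != model.B.shape[0]:
        raise ValueError(
            f"feature count {X_std.shape[1]} does not match model ({model.B.shape[0]})"
        )
    return X_std @ model.B


def nmse(Y_test: np.ndarray, Y_hat: np.ndarray) -> float:
    """Normalized mean squared error, pooled over all matrix cells.

    NMSE = sum (Y - Yhat)^2 / sum (Y - colmean(Y))^2, so the predictor that
    outputs the test-set column means scores exactly 1.
    """
    Y_test = np.asarray(Y_test, dtype=float)
    Y_hat = np.asarray(Y_hat, dtype=float)
    if Y_test.shape != Y_hat.shape:
        raise ValueError("shape mismatch between Y_test and Y_hat")
    denom = float(((Y_test - Y_test.mean(axis=0)) ** 2).sum())
    if denom == 0:
        raise ValueError("constant Y_test: NMSE undefined")
    return float(((Y_test - Y_hat) ** 2).sum()) / denom
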