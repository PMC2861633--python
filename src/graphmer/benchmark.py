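"""End-to-end planted-motif benchmarks on synthetic data.

These routines run the whole pipeline — generate promoters/expression with
planted motifs, count and filter k-mers, build the k-mer graph, fit
(graph-regularized) SIMPLS — and score how well the model recovers the
planted structure: CV-chosen number of factors, trajectory correlations,
consensus containment and 1-mutant neighborhood capture in the top-50
graph-mers, and conservation-score calibration on synthetic ortholog pairs.

The benchmark study conditions: 1000 genes x 12 timepoints, 500 bp promoters
at 36% GC, two planted motifs (CG-rich GCGCGC and E-box CACGTG) with
orthogonal unit-norm trajectories, 4 sites per target promoter, 20% target
genes per motif, per-base site mutation rate 1/6, expression noise sd 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_prep import standardize
from .graph_pls import fit_graph_pls
from .kmer_features import KmerMatrix, build_background, count_kmers, zscore_filter
from .kmer_graph import KmerGraph, build_graph, revcomp
from .model_selection import cross_validate, randomize_pairing
from .motif_extraction import top_kmers
from .synthetic_data import (
    SyntheticDataset,
    SyntheticSpec,
    default_motifs,
    generate,
    generate_ortholog_pairs,
)
from .validation_stats import mcs

# model defaults used throughout the benchmark
LAMBDA_LASSO = 0.1
LAMBDA_GRAPH = 5.0
THETA = 2
TOP_M = 2000
N_TOP = 50


def benchmark_spec(seed: int, n_genes: int = 1000, n_timepoints: int = 12) -> SyntheticSpec:
    """The frozen study conditions for one benchmark replicate."""
    return SyntheticSpec(n_genes=n_genes, n_timepoints=n_timepoints, seed=seed)


@dataclass
class PreparedData:
    dataset: SyntheticDataset
    features: KmerMatrix
    graph: KmerGraph
    X: np.ndarray  # raw counts, dense
    Y: np.ndarray  # raw expression


def prepare(spec: SyntheticSpec, top_m: int = TOP_M, theta: int = THETA) -> PreparedData:
    """Generate data and run the feature stage (count, filter, graph)."""
    dataset = generate(spec)
    km = count_kmers(dataset.promoters)
    bg = build_background(dataset.exons, n_shuffles=100, seed=spec.seed)
    filtered, _ = zscore_filter(km, bg, top_m=top_m)
    graph = build_graph(filtered.kmers, theta=theta)
    return PreparedData(
        dataset, filtered, graph, filtered.dense(), dataset.expression.values
    )


def one_mutant_classes(consensus: str) -> list[str]:
    """Reverse-complement equivalence classes of the consensus's 1-mutants."""
    strings = set()
    for i, b in enumerate(consensus):
        for c in "ACGT":
            if c != b:
                strings.add(consensus[:i] + c + consensus[i + 1 :])
    strings |= {revcomp(s) for s in strings}
    strings -= {consensus, revcomp(consensus)}
    return sorted({min(s, revcomp(s)) for s in strings})


@dataclass
class FactorRecovery:
    factor: int
    motif_index: int
    consensus: str
    trajectory_corr: float  # signed corr(c_i, planted trajectory)
    consensus_in_top: bool
    neighborhood_capture: float  # fraction of feature-set 1-mutant classes in top-50
    n_neighbors_in_features: int


@dataclass
class RecoveryResult:
    seed: int
    chosen_k: int  # by 10-fold CV of standard SIMPLS (sharp minimum)
    cv_mean_simpls: np.ndarray
    cv_mean_graph: np.ndarray | None
    factors: list[FactorRecovery] = field(default_factory=list)
    randomized_nmse_k1: float | None = None


def run_recovery(
    seed: int,
    n_genes: int = 1000,
    include_graph_cv: bool = False,
    include_randomized: bool = True,
    k_max: int = 4,
) -> RecoveryResult:
    """Full planted-motif recovery benchmark for one seed."""
    spec = benchmark_spec(seed, n_genes=n_genes)
    data = prepare(spec)
    truth = data.dataset.ground_truth

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv_s = cross_validate(data.X, data.Y, method="simpls", K_max=k_max,
                              n_folds=10, seed=seed)
        cv_g = None
        if include_graph_cv:
            cv_g = cross_validate(
                data.X, data.Y, method="graph", K_max=k_max, n_folds=10, seed=seed,
                lambda_lasso=LAMBDA_LASSO, lambda_graph=LAMBDA_GRAPH, graph=data.graph,
            )
        X_std, _ = standardize(data.X)
        Y_std, _ = standardize(data.Y)
        model = fit_graph_pls(
            X_std, Y_std, len(spec.motifs),
            lambda_lasso=LAMBDA_LASSO, lambda_graph=LAMBDA_GRAPH, graph=data.graph,
        )

    feature_set = set(data.features.kmers)
    factors: list[FactorRecovery] = []
    for i in range(model.n_factors):
        cors = [
            float(np.corrcoef(model.C[:, i], truth.trajectories[j])[0, 1])
            for j in range(truth.trajectories.shape[0])
        ]
        j = int(np.argmax(np.abs(cors)))
        consensus = truth.consensi[j]
        # the (w, c) sign gauge is arbitrary relative to the planted trajectory:
        # orient w so the factor's positive weights drive the planted pattern
        w = model.W[:, i] * np.sign(cors[j])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = top_kmers(w, data.graph, n=N_TOP, factor=i)
        top = set(gm.kmers)
        cons_in = consensus in top or revcomp(consensus) in top
        nb = one_mutant_classes(consensus)
        nb_in = [c for c in nb if c in feature_set or revcomp(c) in feature_set]
        hits = [c for c in nb_in if c in top or revcomp(c) in top]
        capture = len(hits) / len(nb_in) if nb_in else float("nan")
        factors.append(
            FactorRecovery(i, j, consensus, cors[j], cons_in, capture, len(nb_in))
        )

    randomized = None
    if include_randomized:
        Xp, Yp = randomize_pairing(data.X, data.Y, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv_r = cross_validate(
                Xp, Yp, method="graph", K_max=1, n_folds=10, seed=seed,
                lambda_lasso=LAMBDA_LASSO, lambda_graph=LAMBDA_GRAPH, graph=data.graph,
            )
        randomized = float(cv_r.mean_nmse[1])

    return RecoveryResult(
        seed=seed,
        chosen_k=cv_s.chosen_k,
        cv_mean_simpls=cv_s.mean_nmse,
        cv_mean_graph=None if cv_g is None else cv_g.mean_nmse,
        factors=factors,
        randomized_nmse_k1=randomized,
    )


def _best_window_hamming(consensus: str, pssm_consensus: str) -> int:
    """Min Hamming between the planted consensus (either strand) and any
    same-length window of the reconstructed PSSM consensus."""
    k = len(consensus)
    best = k
    for cand in (consensus, revcomp(consensus)):
        for start in range(0, max(1, len(pssm_consensus) - k + 1)):
            window = pssm_consensus[start : start + k]
            if len(window) < k:
                continue
            best = min(best, sum(a != b for a, b in zip(cand, window)))
    return best


@dataclass
class MotifReconstruction:
    factor: int
    consensus: str
    pssm_consensus: str
    hamming: int
    n_seeds_merged: int


def run_motif_reconstruction(seed: int, n_genes: int = 1000) -> list[MotifReconstruction]:
    """Fit the benchmark model and agglomerate each factor's top module.

    The top MCODE module of each factor's graph-mer is collapsed into a PSSM;
    its consensus should reconstruct the planted consensus (Hamming <= 1 at
    the best alignment, either strand).
    """
    from .motif_extraction import agglomerate, find_modules, promoter_base_frequencies

    spec = benchmark_spec(seed, n_genes=n_genes)
    data = prepare(spec)
    truth = data.dataset.ground_truth
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X_std, _ = standardize(data.X)
        Y_std, _ = standardize(data.Y)
        model = fit_graph_pls(
            X_std, Y_std, len(spec.motifs),
            lambda_lasso=LAMBDA_LASSO, lambda_graph=LAMBDA_GRAPH, graph=data.graph,
        )
    q = promoter_base_frequencies(data.dataset.promoters)
    out: list[MotifReconstruction] = []
    for i in range(model.n_factors):
        cors = [
            float(np.corrcoef(model.C[:, i], truth.trajectories[j])[0, 1])
            for j in range(truth.trajectories.shape[0])
        ]
        j = int(np.argmax(np.abs(cors)))
        consensus = truth.consensi[j]
        w = model.W[:, i] * np.sign(cors[j])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = top_kmers(w, data.graph, n=N_TOP, factor=i)
        modules = find_modules(gm)
        if not modules:
            out.append(MotifReconstruction(i, consensus, "", len(consensus), 0))
            continue
        # the top-scoring module containing the strongest weights
        pssm = agglomerate(
            modules[0], promoters=data.dataset.promoters, background=q
        )
        out.append(
            MotifReconstruction(
                i, consensus, pssm.consensus,
                _best_window_hamming(consensus, pssm.consensus), len(modules[0]),
            )
        )
    return out


@dataclass
class MonotonicityResult:
    lasso_grid: list[float]
    nnz: list[int]
    graph_grid: list[float]
    smoothness: list[float]


def run_monotonicity(
    seed: int,
    n_genes: int = 1000,
    lasso_grid: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
    graph_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0),
) -> MonotonicityResult:
    """Sparsity vs lambda_lasso and smoothness vs lambda_graph on fixed data.

    Each penalty is swept with the other held at zero to isolate its effect.
    """
    spec = benchmark_spec(seed, n_genes=n_genes)
    data = prepare(spec)
    X, _ = standardize(data.X)
    Y, _ = standardize(data.Y)
    L = data.graph.laplacian
    nnz = []
    for ll in lasso_grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_graph_pls(X, Y, 1, lambda_lasso=ll, lambda_graph=0.0)
        nnz.append(int(np.count_nonzero(m.W[:, 0])))
    smooth = []
    for lg in graph_grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_graph_pls(X, Y, 1, lambda_lasso=0.0, lambda_graph=lg, graph=data.graph)
        smooth.append(float(m.W[:, 0] @ (L @ m.W[:, 0])))
    return MonotonicityResult(list(lasso_grid), nnz, list(graph_grid), smooth)


@dataclass
class ConservationResult:
    seed: int
    planted: dict[str, float]  # consensus -> MCS z
    random_q95: float
    p_hat: float


def run_conservation(
    seed: int,
    n_genes: int = 400,
    conservation_prob: float = 0.8,
    n_random: int = 500,
) -> ConservationResult:
    """MCS calibration on synthetic ortholog pairs.

    Planted occurrences are conserved with probability ``conservation_prob``
    while the background conserves only by chance; the planted consensus
    should score far above the random-k-mer z distribution.
    """
    spec = benchmark_spec(seed, n_genes=n_genes)
    dataset = generate(spec)
    ortho, omap = generate_ortholog_pairs(dataset, conservation_prob)
    planted = {}
    q95 = np.nan
    p_hat = np.nan
    for idx, consensus in enumerate(dataset.ground_truth.consensi):
        res = mcs(
            consensus, dataset.promoters, ortho, omap,
            n_random=n_random, seed=seed, keep_random=True,
        )
        planted[consensus] = float(res.z)
        if idx == 0:
            q95 = float(np.percentile(res.random_zs, 95))
            p_hat = float(res.p_hat)
    return ConservationResult(seed, planted, q95, p_hat)
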