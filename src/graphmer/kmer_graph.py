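"""Reverse-complement-aware Hamming graph over retained k-mers.

Two k-mers are joined by an (unweighted, undirected) edge when the minimum of
Hamming(a, b) and Hamming(a, revcomp(b)) is below a threshold theta.  The
graph Laplacian L = D - A supplies the smoothness quadratic form
w' L w = sum over edges (w_i - w_j)^2 used to regularize the PLS weight
vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .kmer_features import encode_sequence

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    """Reverse complement of a k-mer over {A,C,G,T}."""
    if set(s) - set("ACGT"):
        raise ValueError(f"invalid characters in k-mer {s!r}")
    return s.translate(_COMPLEMENT)[::-1]


def kmer_distance(a: str, b: str, cross_length: bool = False) -> float:
    """min(Hamming(a, b), Hamming(a, revcomp(b))); symmetric.

    Length mismatch returns +inf unless ``cross_length`` is set, in which case
    the shorter k-mer is aligned against both end-anchored windows of the
    longer and the minimum is taken.
    """
    if len(a) != len(b):
        if not cross_length:
            return math.inf
        short, long_ = (a, b) if len(a) < len(b) else (b, a)
        return min(
            kmer_distance(short, long_[: len(short)]),
            kmer_distance(short, long_[-len(short) :]),
        )
    rb = revcomp(b)
    h1 = sum(x != y for x, y in zip(a, b))
    h2 = sum(x != y for x, y in zip(a, rb))
    return float(min(h1, h2))


@dataclass
class KmerGraph:
    """Unweighted k-mer similarity graph with its Laplacian."""

    kmers: list[str]
    graph: nx.Graph
    laplacian: sp.csr_matrix

    @property
    def n_nodes(self) -> int:
        return len(self.kmers)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([self.graph.degree(s) for s in self.kmers])

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.kmers)}


def _pairwise_min_hamming(codes: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Pairwise min(Hamming, Hamming-vs-revcomp) within one k-mer length."""
    m, k = codes.shape
    rc = (3 - codes)[:, ::-1]
    out = np.empty((m, m), dtype=np.int16)
    for start in range(0, m, chunk):
        block = codes[start : start + chunk]
        d1 = (block[:, None, :] != codes[None, :, :]).sum(axis=2)
        d2 = (block[:, None, :] != rc[None, :, :]).sum(axis=2)
        out[start : start + chunk] = np.minimum(d1, d2)
    return out


def build_graph(kmers, theta: int = 2, cross_length: bool = False) -> KmerGraph:
    """Build the k-mer graph: edge (i, j) iff kmer_distance(i, j) < theta."""
    if theta < 1:
        raise ValueError("theta must be >= 1")
    kmers = list(kmers)
    g = nx.Graph()
    g.add_nodes_from(kmers)

    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(kmers):
        by_len.setdefault(len(s), []).append(i)

    for indices in by_len.values():
        codes = np.stack([encode_sequence(kmers[i]) for i in indices]).astype(np.int8)
        dist = _pairwise_min_hamming(codes)
        ii, jj = np.nonzero(dist < theta)
        for a, b in zip(ii, jj):
            if a < b:
                g.add_edge(kmers[indices[a]], kmers[indices[b]])

    if cross_length:
        lengths = sorted(by_len)
        for la, lb in [(x, y) for x in lengths for y in lengths if x < y]:
            for i in by_len[la]:
                for j in by_len[lb]:
                    if kmer_distance(kmers[i], kmers[j], cross_length=True) < theta:
                        g.add_edge(kmers[i], kmers[j])

    if kmers:
        lap = sp.csr_matrix(nx.laplacian_matrix(g, nodelist=kmers), dtype=float)
    else:
        lap = sp.csr_matrix((0, 0))
    return KmerGraph(kmers, g, lap)


def smoothness(w: np.ndarray, g: KmerGraph) -> float:
    """Quadratic form w' L w (equals the sum of squared edge differences)."""
    w = np.asarray(w, dtype=float)
    if w.size != g.n_nodes:
        raise ValueError(f"weight vector length {w.size} != node count {g.n_nodes}")
    return float(w @ (g.laplacian @ w))


def write_graphml(g: KmerGraph, path, weights: np.ndarray | None = None) -> None:
    """Export the graph (optionally with per-node PLS weights) as GraphML."""
    out = g.graph.copy()
    if weights is not None:
        for s, w in zip(g.kmers, np.asarray(weights, dtype=float)):
            out.nodes[s]["weight"] = float(w)
    nx.write_graphml(out, str(path))


def write_sif(g: KmerGraph, path, relation: str = "hd") -> None:
    """Export edges in Cytoscape SIF format; isolated nodes on their own line."""
    with open(path, "w") as fh:
        for a, b in g.graph.edges():
            fh.write(f"{a}\t{relation}\t{b}\n")
        for node in g.graph.nodes():
            if g.graph.degree(node) == 0:
                fh.write(f"{node}\n")
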