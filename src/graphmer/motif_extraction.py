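"""From motif weight vectors to PSSMs.

A fitted factor's weight vector is read as a "graph-mer": the top-weighted
k-mers with the induced similarity subgraph.  Dense modules in that subgraph
(found with the MCODE vertex-weighting algorithm) are each collapsed into a
position-specific scoring matrix by greedy agglomeration under a
Jensen-Shannon divergence that allows offsets and pads flanks with the
background base distribution.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data_prep import PromoterSet
from .kmer_graph import KmerGraph, revcomp

BASES = "ACGT"
UNIFORM = np.full(4, 0.25)


@dataclass
class GraphMer:
    """Top-weighted k-mers of one latent factor with their induced subgraph.

    ``sign`` records the orientation of the weight vector that was analyzed:
    the per-factor (w, c) sign gauge is arbitrary, and motifs live on the
    side of w that carries the concentrated weight mass (the paired
    trajectory for interpretation is sign * c).
    """

    factor: int
    kmers: list[str]
    weights: np.ndarray
    graph: nx.Graph
    sign: int = 1


@dataclass
class Pssm:
    """Row-stochastic position x base probability table.

    ``target_count`` is the number of supporting promoters; ``kmers`` records
    the seed k-mers merged into this matrix.
    """

    probs: np.ndarray  # length x 4
    target_count: int
    kmers: list[str] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PSSM must be a length x 4 table")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PSSM rows must sum to 1")
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.probs.argmax(axis=1))


def top_kmers(
    w: np.ndarray,
    graph: KmerGraph,
    n: int = 50,
    factor: int = 0,
    include_negative: bool = False,
) -> GraphMer:
    """Top-n k-mers by signed weight (lexicographic tie-break).

    Negative-weight k-mers are excluded by default: the graph-mer is the set
    of k-mers that drive the factor's expression pattern.  Warns and returns
    what is available when fewer than n qualify.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = np.asarray(w, dtype=float)
    if w.size != graph.n_nodes:
        raise ValueError("weight vector does not match graph")
    candidates = [
        i for i in range(w.size) if (w[i] != 0 if include_negative else w[i] > 0)
    ]
    candidates.sort(key=lambda i: (-w[i], graph.kmers[i]))
    if len(candidates) < n:
        warnings.warn(
            f"only {len(candidates)} qualifying k-mers for a top-{n} graph-mer"
        )
    chosen = candidates[:n]
    names = [graph.kmers[i] for i in chosen]
    sub = graph.graph.subgraph(names).copy()
    return GraphMer(factor, names, w[chosen], sub)


def _mcode_scores(g: nx.Graph) -> dict:
    """MCODE vertex weighting: highest-k-core number of the closed
    neighborhood times the density of that core."""
    scores = {}
    for v in g.nodes():
        nbhd = [v] + list(g.neighbors(v))
        h = g.subgraph(nbhd)
        if h.number_of_edges() == 0:
            scores[v] = 0.0
            continue
        core = nx.core_number(h)
        kmax = max(core.values())
        core_nodes = [u for u, c in core.items() if c >= kmax]
        hc = h.subgraph(core_nodes)
        nn = hc.number_of_nodes()
        density = 2.0 * hc.number_of_edges() / (nn * (nn - 1)) if nn > 1 else 0.0
        scores[v] = kmax * density
    return scores


def find_modules(
    graph: nx.Graph | GraphMer, vwp: float = 0.2, haircut: bool = True
) -> list[list[str]]:
    """Dense k-mer modules via the MCODE molecular-complex algorithm.

    Seeds at the highest-scoring unassigned node and greedily includes
    neighbors whose vertex score is within ``vwp`` of the seed's.  With
    ``haircut``, members attached to the module by a single edge are removed.
    Singleton modules are discarded; modules are returned by descending seed
    score.
    """
    g = graph.graph if isinstance(graph, GraphMer) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    scores = _mcode_scores(g)
    order = sorted(g.nodes(), key=lambda v: (-scores[v], str(v)))
    assigned: set = set()
    modules: list[list[str]] = []
    for seed in order:
        if seed in assigned or scores[seed] <= 0:
            continue
        threshold = scores[seed] * (1.0 - vwp)
        members = {seed}
        queue = [seed]
        while queue:
            v = queue.pop(0)
            for u in g.neighbors(v):
                if u in assigned or u in members:
                    continue
                if scores[u] >= threshold:
                    members.add(u)
                    queue.append(u)
        if haircut and len(members) > 2:
            sub = g.subgraph(members)
            members = {v for v in members if sub.degree(v) >= 2}
        assigned |= members
        if len(members) >= 2:
            modules.append(sorted(members, key=lambda v: (-scores[v], str(v))))
    return modules


def pssm_from_kmer(
    s: str,
    epsilon: float = 0.1,
    background: np.ndarray | None = None,
    promoters: PromoterSet | None = None,
    target_count: int | None = None,
) -> Pssm:
    """Seed PSSM for a single k-mer, smoothed with background probabilities.

    theta_j(b) = (1 - epsilon) [b == s_j] + epsilon q(b).  The target count is
    the number of promoters containing the k-mer on the sense strand (at least
    1 by convention).
    """
    if not (0 < epsilon < 1):
        raise ValueError("epsilon must be in (0, 1)")
    q = UNIFORM if background is None else np.asarray(background, dtype=float)
    if q.shape != (4,) or not np.isclose(q.sum(), 1.0):
        raise ValueError("background must be a length-4 distribution")
    probs = np.tile(epsilon * q, (len(s), 1))
    for j, b in enumerate(s):
        probs[j, BASES.index(b)] += 1.0 - epsilon
    if target_count is None:
        if promoters is not None:
            target_count = max(1, sum(s in seq for seq in promoters.sequences))
        else:
            target_count = 1
    return Pssm(probs, target_count, kmers=[s], name=s)


def _entropy2(p: np.ndarray) -> np.ndarray:
    """Row-wise Shannon entropy in bits (0 log 0 = 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(p), 0.0)
    return -t.sum(axis=-1)


def _padded(probs: np.ndarray, start: int, total: int, q: np.ndarray) -> np.ndarray:
    out = np.tile(q, (total, 1))
    out[start : start + probs.shape[0]] = probs
    return out


def pssm_distance(
    p1: Pssm, p2: Pssm, background: np.ndarray | None = None
) -> tuple[float, int]:
    """Minimum-over-offsets Jensen-Shannon divergence between two PSSMs.

    At each offset (position of p2's start relative to p1's, any alignment
    with at least one overlapping column) both matrices are padded to a
    common span with the background distribution, and the distance is the sum
    over positions of H(pi1 th1 + pi2 th2) - pi1 H(th1) - pi2 H(th2) with
    base-2 logs and mixture weights pi_i proportional to target counts.
    Returns (distance, minimizing offset); ties keep the smallest offset
    scanned first (ascending order).
    """
    q = UNIFORM if background is None else np.asarray(background, dtype=float)
    n1, n2 = p1.target_count, p2.target_count
    pi1 = n1 / (n1 + n2)
    pi2 = n2 / (n1 + n2)
    best = (np.inf, 0)
    for offset in range(-(p2.length - 1), p1.length):
        lo = min(0, offset)
        hi = max(p1.length, offset + p2.length)
        total = hi - lo
        a = _padded(p1.probs, -lo, total, q)
        b = _padded(p2.probs, offset - lo, total, q)
        mix = pi1 * a + pi2 * b
        dist = float((_entropy2(mix) - pi1 * _entropy2(a) - pi2 * _entropy2(b)).sum())
        if dist < best[0] - 1e-15:
            best = (dist, offset)
    return best


def merge_pssms(
    p1: Pssm, p2: Pssm, background: np.ndarray | None = None, offset: int | None = None
) -> Pssm:
    """Mixture-merge two PSSMs at their best (or given) offset.

    The merged table is the position-wise target-count-weighted mixture over
    the padded common span; the merged target count is the sum.
    """
    q = UNIFORM if background is None else np.asarray(background, dtype=float)
    if offset is None:
        _, offset = pssm_distance(p1, p2, background=q)
    lo = min(0, offset)
    hi = max(p1.length, offset + p2.length)
    total = hi - lo
    a = _padded(p1.probs, -lo, total, q)
    b = _padded(p2.probs, offset - lo, total, q)
    pi1 = p1.target_count / (p1.target_count + p2.target_count)
    merged = pi1 * a + (1 - pi1) * b
    return Pssm(
        merged,
        p1.target_count + p2.target_count,
        kmers=p1.kmers + p2.kmers,
        name=f"({p1.name}+{p2.name})",
    )


def agglomerate(
    kmers: list[str],
    promoters: PromoterSet | None = None,
    epsilon: float = 0.1,
    background: np.ndarray | None = None,
) -> Pssm:
    """Hierarchical agglomeration of a k-mer cluster into one PSSM.

    Every k-mer seeds a smoothed PSSM; the closest pair under
    :func:`pssm_distance` is merged repeatedly (m - 1 merges for m seeds)
    until a single binding-site model remains.  Deterministic: ties break on
    the smallest pair index.
    """
    if not kmers:
        raise ValueError("empty k-mer cluster")
    pool = [
        pssm_from_kmer(s, epsilon=epsilon, background=background, promoters=promoters)
        for s in kmers
    ]
    while len(pool) > 1:
        best = (np.inf, 0, 1, 0)
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                d, off = pssm_distance(pool[i], pool[j], background=background)
                if d < best[0] - 1e-15:
                    best = (d, i, j, off)
        _, i, j, off = best
        merged = merge_pssms(pool[i], pool[j], background=background, offset=off)
        pool = [p for idx, p in enumerate(pool) if idx not in (i, j)] + [merged]
    return pool[0]


def export_graphmer(gm: GraphMer, path) -> None:
    """Write a graph-mer as GraphML with per-node PLS weights."""
    out = gm.graph.copy()
    for s, w in zip(gm.kmers, gm.weights):
        out.nodes[s]["weight"] = float(w)
    nx.write_graphml(out, str(path))


def promoter_base_frequencies(promoters: PromoterSet) -> np.ndarray:
    """Mononucleotide frequencies over all promoter bases (N ignored)."""
    counts = np.zeros(4)
    for seq in promoters.sequences:
        for j, b in enumerate(BASES):
            counts[j] += seq.count(b)
    total = counts.sum()
    if total == 0:
        raise ValueError("no A/C/G/T bases in promoter set")
    return counts / total


def write_meme(pssms: list[Pssm], path, background: np.ndarray | None = None) -> None:
    """Write motifs in MEME minimal format (nsites = target count)."""
    q = UNIFORM if background is None else np.asarray(background, dtype=float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {q[j]:.6f}" for j, b in enumerate(BASES)) + "\n\n")
        for idx, p in enumerate(pssms):
            name = p.name or f"motif_{idx + 1}"
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.length} "
                f"nsites= {p.target_count} E= 0\n"
            )
            for row in p.probs:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[Pssm]:
    """Parse a MEME minimal-format motif file."""
    pssms: list[Pssm] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else ""
            i += 1
            header = lines[i].strip()
            m = re.search(r"w=\s*(\d+)", header)
            ns = re.search(r"nsites=\s*(\d+)", header)
            width = int(m.group(1))
            nsites = int(ns.group(1)) if ns else 1
            rows = []
            for j in range(width):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            probs = np.asarray(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            pssms.append(Pssm(probs, max(1, nsites), name=name))
            i += width
        i += 1
    return pssms


def extract_motifs(
    w: np.ndarray,
    graph: KmerGraph,
    promoters: PromoterSet,
    n_top: int = 50,
    vwp: float = 0.2,
    haircut: bool = True,
    epsilon: float = 0.1,
    factor: int = 0,
    orient: str = "auto",
) -> tuple[GraphMer, list[list[str]], list[Pssm]]:
    """Full per-factor pipeline: graph-mer -> MCODE modules -> PSSMs.

    ``orient`` handles the factor's arbitrary sign gauge: "auto" (default)
    analyzes the side of w carrying the larger squared weight mass — the
    motif-bearing side — while "positive"/"negative" force an orientation.
    The paired expression trajectory for interpretation is ``gm.sign * c``.
    """
    w = np.asarray(w, dtype=float)
    if orient == "auto":
        sign = -1 if (w[w < 0] ** 2).sum() > (w[w > 0] ** 2).sum() else 1
    elif orient == "positive":
        sign = 1
    elif orient == "negative":
        sign = -1
    else:
        raise ValueError(f"unknown orientation {orient!r}")
    gm = top_kmers(sign * w, graph, n=n_top, factor=factor)
    gm.sign = sign
    if gm.graph.number_of_nodes() == 0:
        return gm, [], []
    modules = find_modules(gm, vwp=vwp, haircut=haircut)
    q = promoter_base_frequencies(promoters)
    pssms = [
        agglomerate(cluster, promoters=promoters, epsilon=epsilon, background=q)
        for cluster in modules
    ]
    for idx, p in enumerate(pssms):
        p.name = f"factor{factor + 1}_motif{idx + 1}_{p.consensus}"
    return gm, modules, pssms
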