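"""Positional-bias and conservation statistics for candidate motifs.

Occurrences are counted on both strands (a k-mer or its reverse complement).
Distances are measured in base pairs upstream of the TSS: an occurrence whose
TSS-proximal end is the base immediately upstream of the TSS has distance 1.
The motif conservation score (MCS) is a z-score comparing a k-mer's
ortholog-conservation rate against the expected rate estimated from random
k-mers of the same length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_prep import PromoterSet
from .kmer_features import decode_kmer
from .kmer_graph import revcomp


def _occurrence_starts(seq: str, kmer: str, both_strands: bool = True) -> list[int]:
    """0-based start positions of (possibly overlapping) matches."""
    patterns = {kmer}
    if both_strands:
        patterns.add(revcomp(kmer))
    starts = []
    for pat in patterns:
        j = seq.find(pat)
        while j != -1:
            starts.append(j)
            j = seq.find(pat, j + 1)
    return sorted(starts)


def _count_occurrences(seq: str, kmer: str, both_strands: bool = True) -> int:
    return len(_occurrence_starts(seq, kmer, both_strands))


def _present(seq: str, kmer: str, both_strands: bool = True) -> bool:
    return kmer in seq or (both_strands and revcomp(kmer) in seq)


def tss_distance_distribution(
    motif_kmers: Iterable[str],
    promoters: PromoterSet,
    gene_set: Sequence[str],
    bin_width: int = 50,
) -> tuple[list[int], pd.DataFrame]:
    """Upstream distances of every motif occurrence in the given genes.

    Distance is the position (1-based, increasing upstream) of the
    occurrence's TSS-proximal end.  Returns raw distances plus a binned
    histogram.
    """
    mapping = promoters.mapping
    genes = [g for g in gene_set if g in mapping]
    if not genes:
        raise ValueError("gene set has no genes with promoters")
    kmers = list(motif_kmers)
    distances: list[int] = []
    for g in genes:
        seq = mapping[g]
        L = len(seq)
        for kmer in kmers:
            for j in _occurrence_starts(seq, kmer):
                distances.append(L - (j + len(kmer) - 1))
    if distances:
        top = (max(distances) // bin_width + 1) * bin_width
        edges = np.arange(0, top + bin_width, bin_width)
        counts, _ = np.histogram(distances, bins=edges)
        hist = pd.DataFrame(
            {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
        )
    else:
        hist = pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    return distances, hist


@dataclass
class PositionalBiasResult:
    frac_in_window: float
    frac_out_window: float
    statistic: float
    p_value: float
    window: int


def positional_bias_test(
    dist_in_set: Sequence[float],
    dist_out_set: Sequence[float],
    window: int = 200,
) -> PositionalBiasResult:
    """Does the motif sit closer to the TSS in one gene group?

    Reports the fraction of occurrences within ``window`` bp for each group
    and a one-sided two-sample KS p-value for the in-set distances being
    stochastically smaller (closer to the TSS).
    """
    d_in = np.asarray(dist_in_set, dtype=float)
    d_out = np.asarray(dist_out_set, dtype=float)
    if d_in.size == 0 or d_out.size == 0:
        raise ValueError("both distance lists must be non-empty")
    frac_in = float((d_in <= window).mean())
    frac_out = float((d_out <= window).mean())
    # alternative='greater': CDF of d_in lies above that of d_out, i.e.
    # in-set distances stochastically smaller
    res = stats.ks_2samp(d_in, d_out, alternative="greater")
    return PositionalBiasResult(frac_in, frac_out, float(res.statistic), float(res.pvalue), window)


@dataclass
class McsResult:
    kmer: str
    n: int
    n_c: int
    p_hat: float
    z: float
    flag: str
    random_zs: np.ndarray | None = None

    @property
    def rate(self) -> float:
        return self.n_c / self.n if self.n else math.nan


def mcs_zscore(n_c: int, n: int, p_hat: float) -> float:
    """Binomial z for n_c conserved occurrences out of n at expected rate p_hat."""
    if n == 0:
        return math.nan
    if p_hat <= 0:
        return math.inf if n_c > 0 else 0.0
    if p_hat >= 1:
        return -math.inf if n_c < n else 0.0
    return (n_c - n * p_hat) / math.sqrt(n * p_hat * (1.0 - p_hat))


def _conservation_counts(
    kmer: str, pairs: list[tuple[str, str]]
) -> tuple[int, int]:
    """(total occurrences, conserved occurrences) over (promoter, ortholog) pairs.

    An occurrence is conserved when the k-mer (either strand) is present
    anywhere in the ortholog's promoter.
    """
    n = n_c = 0
    for seq_a, seq_b in pairs:
        occ = _count_occurrences(seq_a, kmer)
        if occ == 0:
            continue
        n += occ
        if _present(seq_b, kmer):
            n_c += occ
    return n, n_c


def _ortholog_pairs(
    promoters_a: PromoterSet,
    promoters_b: PromoterSet,
    ortholog_map: Mapping[str, str],
) -> list[tuple[str, str]]:
    if not ortholog_map:
        raise ValueError("empty ortholog map")
    map_a = promoters_a.mapping
    map_b = promoters_b.mapping
    pairs = [
        (map_a[g], map_b[ortholog_map[g]])
        for g in promoters_a.gene_ids
        if g in ortholog_map and ortholog_map[g] in map_b
    ]
    if not pairs:
        raise ValueError("no genes with orthologous promoters")
    return pairs


def mcs(
    kmer: str,
    promoters_a: PromoterSet,
    promoters_b: PromoterSet,
    ortholog_map: Mapping[str, str],
    n_random: int = 500,
    seed: int = 0,
    keep_random: bool = False,
) -> McsResult:
    """Motif conservation score: z for the k-mer's conservation rate.

    The expected rate p_hat is the mean conservation rate of ``n_random``
    uniformly drawn random k-mers of the same length (seeded, so the same
    seed reuses the same background draw).  Occurrences are counted only in
    genes that have an ortholog.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    pairs = _ortholog_pairs(promoters_a, promoters_b, ortholog_map)
    n, n_c = _conservation_counts(kmer, pairs)

    k = len(kmer)
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4**k, size=n_random)
    rates = []
    random_counts = []
    for code in codes:
        rk = decode_kmer(int(code), k)
        rn, rnc = _conservation_counts(rk, pairs)
        random_counts.append((rn, rnc))
        if rn > 0:
            rates.append(rnc / rn)
    p_hat = float(np.mean(rates)) if rates else math.nan

    flag = ""
    if n == 0:
        flag = "no_occurrences"
        z = math.nan
    elif not math.isfinite(p_hat):
        flag = "no_background_occurrences"
        z = math.nan
    else:
        z = mcs_zscore(n_c, n, p_hat)
        if math.isinf(z):
            flag = "degenerate_background_rate"
    random_zs = None
    if keep_random and math.isfinite(p_hat):
        random_zs = np.array(
            [mcs_zscore(rnc, rn, p_hat) for rn, rnc in random_counts if rn > 0]
        )
    return McsResult(kmer, n, n_c, p_hat, z, flag, random_zs)


@dataclass
class McsContrastResult:
    delta: pd.Series  # per-kmer MCS_in - MCS_out
    top_kmers: list[str]
    statistic: float
    p_value: float


def mcs_contrast_ks(
    kmers: Sequence[str],
    weights: np.ndarray,
    mcs_in: Mapping[str, float],
    mcs_out: Mapping[str, float],
    top_n: int = 50,
) -> McsContrastResult:
    """One-sided KS: do the top-weighted k-mers have larger MCS contrast?

    delta(kmer) = MCS_in - MCS_out; the top-n k-mers by positive weight are
    tested for being stochastically greater than the remainder.
    """
    weights = np.asarray(weights, dtype=float)
    order = sorted(
        (i for i in range(len(kmers)) if weights[i] > 0),
        key=lambda i: (-weights[i], kmers[i]),
    )
    top = [kmers[i] for i in order[:top_n]]
    top_set = set(top)
    rest = [s for s in kmers if s not in top_set]
    if set(rest) & top_set:
        raise RuntimeError("top and remainder k-mer sets overlap")
    delta = pd.Series({s: mcs_in[s] - mcs_out[s] for s in kmers}, name="delta_mcs")
    d_top = delta[top].dropna().to_numpy()
    d_rest = delta[rest].dropna().to_numpy()
    if d_top.size < 2 or d_rest.size < 2:
        warnings.warn("degenerate group size for KS contrast")
        return McsContrastResult(delta, top, math.nan, math.nan)
    # alternative='less': CDF of the top group lies below, i.e. the top-n
    # deltas are stochastically greater
    res = stats.ks_2samp(d_top, d_rest, alternative="less")
    return McsContrastResult(delta, top, float(res.statistic), float(res.pvalue))


def kmer_hit_enrichment(
    gene_set: Sequence[str], hit_genes: Sequence[str], universe: Sequence[str]
) -> float:
    """Upper-tail hypergeometric p for gene-set / k-mer-hit overlap."""
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    gs = set(gene_set) & universe_set
    if set(gene_set) - universe_set:
        raise ValueError("gene_set must be a subset of the universe")
    hits = set(hit_genes) & universe_set
    overlap = len(gs & hits)
    M, n, N = len(universe_set), len(hits), len(gs)
    return float(stats.hypergeom.sf(overlap - 1, M, n, N))


def load_ortholog_map(path) -> dict[str, str]:
    """Read a two-column geneA<TAB>geneB ortholog map."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("ortholog map needs two tab-separated columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))
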