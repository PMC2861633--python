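"""k-mer counting and background-based feature filtering.

Builds the gene x k-mer count matrix from promoter sequences (overlapping
occurrences, sense strand as written) and removes k-mers whose promoter counts
are not clearly above what shuffled exon sequences would produce, ranked by a
binomial z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_prep import PromoterSet

_BASES = "ACGT"
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else (N) as 4."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def window_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all valid length-k windows (windows containing N dropped)."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        base = enc[i : i + n]
        codes = codes * 4 + base
        valid &= base < 4
    return codes[valid]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


@dataclass
class KmerMatrix:
    """Gene x k-mer matrix of overlapping occurrence counts.

    ``window_totals`` maps each k to the total number of valid length-k
    windows across all promoters (the binomial trial count for the
    background z-score).
    """

    gene_ids: list[str]
    kmers: list[str]
    counts: sp.csr_matrix
    window_totals: dict[int, int] | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.kmers)):
            raise ValueError("count matrix shape does not match gene/kmer lists")
        if len(set(self.kmers)) != len(self.kmers):
            raise ValueError("duplicate k-mers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_kmers(self) -> int:
        return len(self.kmers)

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)

    def column_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def select(self, kmer_subset: Sequence[str]) -> "KmerMatrix":
        index = {s: j for j, s in enumerate(self.kmers)}
        cols = [index[s] for s in kmer_subset]
        return KmerMatrix(
            list(self.gene_ids),
            list(kmer_subset),
            self.counts[:, cols].tocsr(),
            window_totals=self.window_totals,
        )

    def write(self, triplet_path, kmer_path) -> None:
        """Serialize as sparse triplets (gene, kmer, count) plus a k-mer list."""
        coo = self.counts.tocoo()
        with open(triplet_path, "w") as fh:
            fh.write("gene\tkmer\tcount\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{self.gene_ids[i]}\t{self.kmers[j]}\t{int(v)}\n")
        with open(kmer_path, "w") as fh:
            for s in self.kmers:
                fh.write(s + "\n")

    @classmethod
    def read(cls, triplet_path, kmer_path, gene_ids: Sequence[str] | None = None) -> "KmerMatrix":
        with open(kmer_path) as fh:
            kmers = [line.strip() for line in fh if line.strip()]
        frame = pd.read_csv(triplet_path, sep="\t")
        if gene_ids is None:
            gene_ids = list(dict.fromkeys(frame["gene"].astype(str)))
        gi = {g: i for i, g in enumerate(gene_ids)}
        kj = {s: j for j, s in enumerate(kmers)}
        rows = frame["gene"].astype(str).map(gi).to_numpy()
        cols = frame["kmer"].map(kj).to_numpy()
        mat = sp.coo_matrix(
            (frame["count"].to_numpy(), (rows, cols)), shape=(len(gene_ids), len(kmers))
        )
        return cls(list(gene_ids), kmers, mat.tocsr())


@dataclass
class BackgroundModel:
    """Background k-mer frequencies estimated from shuffled exon sequences.

    ``p(kmer)`` is (count in all shuffled sequences) / N, with N the total
    number of shuffled bases.
    """

    counts: dict[int, np.ndarray]  # k -> bincount over 4**k codes
    total_length: int
    n_shuffles: int

    def p(self, kmer: str) -> float:
        k = len(kmer)
        if k not in self.counts:
            raise KeyError(f"no background counts for k={k}")
        code = int(window_codes(encode_sequence(kmer), k)[0])
        return float(self.counts[k][code]) / self.total_length

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#total_length\t{self.total_length}\n")
            fh.write(f"#n_shuffles\t{self.n_shuffles}\n")
            fh.write("kmer\tcount\n")
            for k, arr in sorted(self.counts.items()):
                for code in np.flatnonzero(arr):
                    fh.write(f"{decode_kmer(int(code), k)}\t{int(arr[code])}\n")

    @classmethod
    def read(cls, path) -> "BackgroundModel":
        total = n_shuffles = None
        rows: list[tuple[str, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#total_length"):
                    total = int(line.split("\t")[1])
                elif line.startswith("#n_shuffles"):
                    n_shuffles = int(line.split("\t")[1])
                elif line and not line.startswith("#") and not line.startswith("kmer\t"):
                    s, c = line.split("\t")
                    rows.append((s, int(c)))
        if total is None or n_shuffles is None:
            raise ValueError("malformed background model file")
        counts: dict[int, np.ndarray] = {}
        for s, c in rows:
            k = len(s)
            counts.setdefault(k, np.zeros(4**k, dtype=np.int64))
            counts[k][int(window_codes(encode_sequence(s), k)[0])] = c
        return cls(counts, total, n_shuffles)


def count_kmers(promoters: PromoterSet, k_set: Iterable[int] = (6, 7)) -> KmerMatrix:
    """Count overlapping sense-strand k-mer occurrences per promoter.

    Only k-mers observed in at least one promoter are instantiated as columns.
    Column order is by k-mer length, then lexicographic.
    """
    if len(promoters) == 0:
        raise ValueError("empty promoter set")
    k_list = sorted(set(int(k) for k in k_set))
    encoded = [encode_sequence(s) for s in promoters.sequences]

    blocks = []
    kmers: list[str] = []
    for k in k_list:
        rows, cols, vals = [], [], []
        seen_codes: dict[int, int] = {}
        per_gene = []
        for i, enc in enumerate(encoded):
            codes, counts = np.unique(window_codes(enc, k), return_counts=True)
            per_gene.append((i, codes, counts))
            for code in codes:
                if int(code) not in seen_codes:
                    seen_codes[int(code)] = 0
        ordered = sorted(seen_codes)
        col_of = {code: j for j, code in enumerate(ordered)}
        for i, codes, counts in per_gene:
            for code, c in zip(codes, counts):
                rows.append(i)
                cols.append(col_of[int(code)])
                vals.append(int(c))
        blocks.append(
            sp.coo_matrix((vals, (rows, cols)), shape=(len(promoters), len(ordered)))
        )
        kmers.extend(decode_kmer(code, k) for code in ordered)
    counts = sp.hstack(blocks).tocsr() if blocks else sp.csr_matrix((len(promoters), 0))
    window_totals = {
        k: int(sum(window_codes(enc, k).size for enc in encoded)) for k in k_list
    }
    return KmerMatrix(list(promoters.gene_ids), kmers, counts, window_totals=window_totals)


def build_background(
    exons: Sequence[str],
    k_set: Iterable[int] = (6, 7),
    n_shuffles: int = 100,
    seed: int = 0,
) -> BackgroundModel:
    """Mononucleotide-shuffle each exon ``n_shuffles`` times and count k-mers.

    Each shuffle preserves the exon's exact base composition.  Counting never
    crosses exon boundaries.  Deterministic given ``seed``.
    """
    if len(exons) == 0:
        raise ValueError("empty exon set")
    k_list = sorted(set(int(k) for k in k_set))
    rng = np.random.default_rng(seed)
    counts = {k: np.zeros(4**k, dtype=np.int64) for k in k_list}
    total = 0
    encoded = [encode_sequence(s) for s in exons]
    for enc in encoded:
        total += enc.size * n_shuffles
        for _ in range(n_shuffles):
            shuffled = rng.permutation(enc)
            for k in k_list:
                codes = window_codes(shuffled, k)
                if codes.size:
                    counts[k] += np.bincount(codes, minlength=4**k)
    return BackgroundModel(counts, total, n_shuffles)


def kmer_zscores(
    km: KmerMatrix, bg: BackgroundModel, n_trials: dict[int, int] | None = None
) -> pd.DataFrame:
    """Binomial z-score per k-mer: z = (n - L p) / sqrt(L p (1 - p)).

    n is the k-mer's total promoter count, p its per-position background
    frequency (shuffled-exon count / shuffled length), and L the number of
    length-k windows in the promoter set (the binomial trial count for the
    observed occurrences).  p = 0 with n > 0 gives +inf (never seen in
    background, always ranked first).
    """
    if n_trials is None:
        n_trials = km.window_totals
    if n_trials is None:
        raise ValueError("promoter window totals unavailable; pass n_trials")
    n = km.column_totals().astype(float)
    L = np.array([float(n_trials[len(s)]) for s in km.kmers])
    p = np.array([bg.p(s) for s in km.kmers])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (n - L * p) / np.sqrt(L * p * (1.0 - p))
    z = np.where((p == 0) & (n > 0), np.inf, z)
    z = np.where((p == 0) & (n == 0), 0.0, z)
    return pd.DataFrame({"kmer": km.kmers, "n": n.astype(int), "p": p, "z": z})


def zscore_filter(
    km: KmerMatrix, bg: BackgroundModel, top_m: int = 2000
) -> tuple[KmerMatrix, pd.DataFrame]:
    """Retain the ``top_m`` k-mers by background z-score.

    Ranking is by descending z with a stable lexicographic tie-break on the
    k-mer string.  Returns the filtered matrix (columns in rank order) and the
    full score table.
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    scores = kmer_zscores(km, bg)
    order = sorted(range(km.n_kmers), key=lambda j: (-scores["z"].iat[j], km.kmers[j]))
    if top_m > km.n_kmers:
        warnings.warn(
            f"top_m={top_m} exceeds available k-mers ({km.n_kmers}); keeping all"
        )
        top_m = km.n_kmers
    chosen = [km.kmers[j] for j in order[:top_m]]
    return km.select(chosen), scores
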