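"""Synthetic promoter/expression fixtures with planted motifs.

Emulates the generative assumption behind the model: promoters are i.i.d.
background sequence; a subset of target genes carries planted (possibly
mutated, possibly reverse-complemented) copies of a consensus motif; each
gene's expression trajectory is a linear combination of the planted copy
counts times per-motif unit-norm trajectories, plus Gaussian noise.  A
companion generator produces ortholog promoters in which planted occurrences
are conserved with a given probability, for conservation-score tests.

Defaults mirror the study conditions the pipeline targets: 1000 genes, 12
timepoints, 500 bp promoters at worm-like 36% GC, two planted motifs (a
CG-rich oocyte-like 6-mer and the E-box CACGTG) with orthogonal trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_prep import ExpressionMatrix, PromoterSet
from .kmer_graph import revcomp

_BASES = "ACGT"


@dataclass
class PlantedMotif:
    """One planted consensus with its driving expression trajectory."""

    consensus: str
    trajectory: np.ndarray  # unit-norm, length n_timepoints
    effect_size: float = 1.0
    copies_per_target: int = 4
    mutation_rate: float = 1.0 / 6.0  # per-base substitution probability per copy
    target_fraction: float = 0.2

    def __post_init__(self) -> None:
        self.trajectory = np.asarray(self.trajectory, dtype=float)
        if not np.isclose(np.linalg.norm(self.trajectory), 1.0, atol=1e-8):
            raise ValueError("trajectory must be unit-norm")
        if not (0 <= self.mutation_rate < 0.5):
            raise ValueError("mutation rate must be in [0, 0.5)")
        if set(self.consensus) - set(_BASES):
            raise ValueError("consensus must be over A/C/G/T")


def default_motifs(n_timepoints: int = 12) -> list[PlantedMotif]:
    """Two orthogonal planted motifs: a CG-rich late riser and a mid-peak E-box."""
    t = np.arange(n_timepoints, dtype=float)
    c1 = t - t.mean()  # monotone rise (oocyte-like)
    c1 /= np.linalg.norm(c1)
    bump = np.exp(-0.5 * ((t - (n_timepoints - 1) / 2) / (n_timepoints / 6)) ** 2)
    bump -= bump.mean()
    bump -= c1 * (c1 @ bump)  # orthogonalize against the riser
    c2 = bump / np.linalg.norm(bump)
    return [
        PlantedMotif("GCGCGC", c1),
        PlantedMotif("CACGTG", c2),
    ]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset (seed fully determines it)."""

    n_genes: int = 1000
    n_timepoints: int = 12
    promoter_length: int = 500
    gc_content: float = 0.36
    noise_sd: float = 0.5
    motifs: list[PlantedMotif] | None = None
    n_exons: int = 200
    exon_length: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motifs is None:
            self.motifs = default_motifs(self.n_timepoints)
        for m in self.motifs:
            if m.trajectory.size != self.n_timepoints:
                raise ValueError("trajectory length must equal n_timepoints")
            if len(m.consensus) > self.promoter_length:
                raise ValueError("promoter too short for planted motif")
        if sum(m.target_fraction for m in self.motifs) > 1:
            raise ValueError("target fractions exceed the gene count")


@dataclass
class PlantedOccurrence:
    gene: str
    motif_index: int
    position: int  # 0-based start in the stored promoter string
    sequence: str  # the string actually inserted (mutated / strand-flipped)
    strand: str  # '+' or '-'


@dataclass
class GroundTruth:
    """Planted positions, realized copies and target memberships."""

    occurrences: list[PlantedOccurrence]
    copy_counts: np.ndarray  # n_genes x n_motifs
    memberships: dict[int, list[str]]  # motif index -> target gene ids
    consensi: list[str]
    trajectories: np.ndarray  # n_motifs x n_timepoints

    def to_json(self, path) -> None:
        payload = {
            "consensi": self.consensi,
            "trajectories": self.trajectories.tolist(),
            "memberships": {str(k): v for k, v in self.memberships.items()},
            "copy_counts": self.copy_counts.tolist(),
            "occurrences": [
                [o.gene, o.motif_index, o.position, o.sequence, o.strand]
                for o in self.occurrences
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            occurrences=[PlantedOccurrence(*row) for row in payload["occurrences"]],
            copy_counts=np.asarray(payload["copy_counts"]),
            memberships={int(k): v for k, v in payload["memberships"].items()},
            consensi=payload["consensi"],
            trajectories=np.asarray(payload["trajectories"]),
        )


@dataclass
class SyntheticDataset:
    promoters: PromoterSet
    expression: ExpressionMatrix
    exons: list[str]
    ground_truth: GroundTruth
    spec: SyntheticSpec

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.promoters.write_fasta(d / "promoters.fasta")
        with open(d / "exons.fasta", "w") as fh:
            for i, s in enumerate(self.exons):
                fh.write(f">exon{i:04d}\n{s}\n")
        self.expression.to_frame().to_csv(d / "expression.tsv", sep="\t")
        self.ground_truth.to_json(d / "ground_truth.json")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_sequences(rng, n: int, length: int, probs: np.ndarray) -> list[str]:
    draws = rng.choice(4, size=(n, length), p=probs)
    lut = np.array(list(_BASES))
    return ["".join(lut[row]) for row in draws]


def _mutate(rng, consensus: str, rate: float) -> str:
    out = []
    for b in consensus:
        if rate > 0 and rng.random() < rate:
            out.append(rng.choice([c for c in _BASES if c != b]))
        else:
            out.append(b)
    return "".join(out)


def _place_nonoverlapping(rng, length: int, k: int, taken: list[tuple[int, int]],
                          max_tries: int = 200) -> int | None:
    for _ in range(max_tries):
        pos = int(rng.integers(0, length - k + 1))
        if all(pos + k <= a or pos >= b for a, b in taken):
            return pos
    return None


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate promoters, expression and ground truth from one seed."""
    rng = np.random.default_rng(spec.seed)
    probs = _base_probs(spec.gc_content)
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    sequences = _random_sequences(rng, spec.n_genes, spec.promoter_length, probs)

    # disjoint target sets per motif
    order = rng.permutation(spec.n_genes)
    memberships: dict[int, list[str]] = {}
    cursor = 0
    for mi, motif in enumerate(spec.motifs):
        n_targets = int(round(motif.target_fraction * spec.n_genes))
        memberships[mi] = [gene_ids[j] for j in order[cursor : cursor + n_targets]]
        cursor += n_targets

    occurrences: list[PlantedOccurrence] = []
    copy_counts = np.zeros((spec.n_genes, len(spec.motifs)), dtype=int)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    seq_chars = {g: list(sequences[gene_index[g]]) for g in gene_ids}
    taken: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    for mi, motif in enumerate(spec.motifs):
        k = len(motif.consensus)
        for g in memberships[mi]:
            for _ in range(motif.copies_per_target):
                variant = _mutate(rng, motif.consensus, motif.mutation_rate)
                strand = "+" if rng.random() < 0.5 else "-"
                inserted = variant if strand == "+" else revcomp(variant)
                pos = _place_nonoverlapping(
                    rng, spec.promoter_length, k, taken[g]
                )
                if pos is None:
                    continue
                taken[g].append((pos, pos + k))
                seq_chars[g][pos : pos + k] = list(inserted)
                occurrences.append(PlantedOccurrence(g, mi, pos, inserted, strand))
                copy_counts[gene_index[g], mi] += 1
    sequences = ["".join(seq_chars[g]) for g in gene_ids]

    trajectories = np.stack([m.trajectory for m in spec.motifs])
    effects = np.array([m.effect_size for m in spec.motifs])
    signal = (copy_counts * effects) @ trajectories
    noise = (
        rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_timepoints))
        if spec.noise_sd > 0
        else 0.0
    )
    values = signal + noise
    labels = [f"t{j:02d}" for j in range(spec.n_timepoints)]
    expression = ExpressionMatrix(gene_ids, values, labels)

    exons = _random_sequences(rng, spec.n_exons, spec.exon_length, probs)
    truth = GroundTruth(
        occurrences,
        copy_counts,
        memberships,
        [m.consensus for m in spec.motifs],
        trajectories,
    )
    return SyntheticDataset(
        PromoterSet(gene_ids, sequences), expression, exons, truth, spec
    )


def generate_ortholog_pairs(
    dataset: SyntheticDataset, conservation_prob: float, seed: int | None = None
) -> tuple[PromoterSet, dict[str, str]]:
    """Fresh background ortholog promoters with probabilistically conserved sites.

    Each planted occurrence is copied (same inserted string, new random
    position) into the gene's ortholog promoter with probability
    ``conservation_prob``.
    """
    if not (0 <= conservation_prob <= 1):
        raise ValueError("conservation_prob must be in [0, 1]")
    spec = dataset.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    probs = _base_probs(spec.gc_content)
    ortho_ids = [g + "_b" for g in dataset.promoters.gene_ids]
    sequences = _random_sequences(rng, spec.n_genes, spec.promoter_length, probs)
    chars = {g: list(s) for g, s in zip(ortho_ids, sequences)}
    taken: dict[str, list[tuple[int, int]]] = {g: [] for g in ortho_ids}
    for occ in dataset.ground_truth.occurrences:
        if rng.random() >= conservation_prob:
            continue
        og = occ.gene + "_b"
        k = len(occ.sequence)
        pos = _place_nonoverlapping(rng, spec.promoter_length, k, taken[og])
        if pos is None:
            continue
        taken[og].append((pos, pos + k))
        chars[og][pos : pos + k] = list(occ.sequence)
    ortho = PromoterSet(ortho_ids, ["".join(chars[g]) for g in ortho_ids])
    ortholog_map = dict(zip(dataset.promoters.gene_ids, ortho_ids))
    return ortho, ortholog_map
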