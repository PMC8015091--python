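"""Synthetic genomes and alignments with known ground truth.

Real inputs for this kind of study are whole-genome assemblies and
mitochondrial alignments; to make every pipeline stage testable without
downloads, this module simulates their relevant statistical structure.

``generate_clade_genomes`` emulates clade-structured k-mer composition
with two layers:

* a base order-m Markov chain over {A,C,G,T}, perturbed in logit space
  once per clade (scale ``clade_divergence``) and again per species
  (smaller scale ``species_divergence``), from which each genome's
  background is sampled;
* a pool of repeat/motif families — random words drawn once per
  simulation — planted into every genome, with per-family log-intensities
  perturbed per clade and per species at the same two scales.

The second layer is what gives clades a signature the score statistic can
see: the score S = (O-E)/(O+E) measures deviation from the empirical
order-(k-2) Markov prediction, so any background chain of order <= k-2 is
cancelled from the signature by construction. Interspersed repeat
families and shared binding-site-like motifs are long-range word
structure of exactly the kind alignment-free k-mer comparison detects in
real genomes, and lineage-specific family expansion is their real
between-clade behaviour. Each genome is finally split into 2-5 records.
The simulator still makes no attempt at fuller realism (no indels, GC
gradients, repeat decay or selection).

``generate_alignment`` produces a gapped alignment by mutating an
ancestral sequence independently per species and site, with a closed-form
expected pairwise identity for checking the identity stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import InvalidParameterError
from .identity import AlignmentBlock
from .kmer import GenomeSequence

__all__ = [
    "CladeSpec",
    "CladeGenomes",
    "generate_clade_genomes",
    "generate_alignment",
    "expected_pairwise_identity",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CladeSpec:
    """Parameters of the clade-structured genome simulation.

    clade_divergence / species_divergence are standard deviations of the
    Gaussian log-space perturbations applied at the clade and species
    level, both to the Markov transition logits and to the repeat-family
    intensities; within-clade divergence must stay below between-clade
    divergence for the planted structure to make sense. genome_length
    must give every order-m context a chance to occur
    (>= 10 * 4**markov_order).

    The repeat layer plants ``n_repeat_families`` random words of length
    ``repeat_length`` covering on average ``repeat_coverage`` of each
    genome. The defaults (40 families of 150 bp covering 35% of the
    genome) are sized after real mammalian assemblies, where interspersed
    repeats cover 40-50% of the genome in dozens of strongly
    lineage-specific subfamilies of roughly SINE-to-LINE-fragment length.
    """

    n_clades: int = 3
    species_per_clade: int = 4
    genome_length: int = 200_000
    markov_order: int = 2
    clade_divergence: float = 0.5
    species_divergence: float = 0.05
    seed: int = 42
    n_repeat_families: int = 40
    repeat_length: int = 150
    repeat_coverage: float = 0.35

    def __post_init__(self):
        if self.n_clades < 2:
            raise InvalidParameterError("need at least 2 clades")
        if self.species_per_clade < 2:
            raise InvalidParameterError("need at least 2 species per clade")
        if self.markov_order < 1:
            raise InvalidParameterError("markov_order must be >= 1")
        if self.clade_divergence <= 0:
            raise InvalidParameterError("clade_divergence must be > 0")
        if not 0 <= self.species_divergence < self.clade_divergence:
            raise InvalidParameterError(
                "species_divergence must satisfy 0 <= s < clade_divergence"
            )
        if self.genome_length < 10 * 4 ** self.markov_order:
            raise InvalidParameterError(
                f"genome_length must be >= {10 * 4 ** self.markov_order} "
                f"for markov_order={self.markov_order}"
            )
        if self.n_repeat_families < 0 or self.repeat_length < 1:
            raise InvalidParameterError("invalid repeat-family settings")
        if not 0.0 <= self.repeat_coverage < 1.0:
            raise InvalidParameterError("repeat_coverage must be in [0, 1)")
        if self.repeat_length >= self.genome_length:
            raise InvalidParameterError("repeat_length must be < genome_length")


class CladeGenomes(NamedTuple):
    genomes: list[GenomeSequence]
    clades: dict[str, int]  # species label -> planted clade index


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(z)
    return p / p.sum(axis=-1, keepdims=True)


def _sample_chain(cum_probs: np.ndarray, length: int, order: int, rng) -> str:
    """Sample one sequence from an order-m chain (cum_probs: [4**m, 4] CDFs)."""
    n_ctx = cum_probs.shape[0]
    mask = n_ctx - 1
    out = np.empty(length, dtype=np.uint8)
    start = rng.integers(0, 4, size=order)
    out[:order] = _BASES[start]
    ctx = 0
    for b in start:
        ctx = ((ctx << 2) | int(b)) & mask
    u = rng.random(length)
    for t in range(order, length):
        b = int(np.searchsorted(cum_probs[ctx], u[t], side="right"))
        b = min(b, 3)
        out[t] = _BASES[b]
        ctx = ((ctx << 2) | b) & mask
    return out.tobytes().decode("ascii")


def _split_records(seq: str, rng) -> list[str]:
    """Split a chromosome into 2-5 records to exercise boundary handling."""
    n_rec = int(rng.integers(2, 6))
    n = len(seq)
    min_len = max(1, min(50, n // (2 * n_rec)))
    while True:
        cuts = np.sort(rng.choice(np.arange(1, n), size=n_rec - 1, replace=False))
        bounds = [0, *cuts.tolist(), n]
        parts = [seq[a:b] for a, b in zip(bounds, bounds[1:])]
        if min(len(p) for p in parts) >= min_len:
            return parts


def _plant_repeats(
    seq: np.ndarray, families: np.ndarray, log_intensity: np.ndarray,
    coverage: float, rng,
) -> np.ndarray:
    """Overwrite random positions with repeat-family words.

    Expected total coverage is ``coverage``; how it is shared between the
    families follows their (perturbed) log-intensities. Overlapping
    insertions may corrupt earlier copies, which is harmless (real repeat
    copies decay too).
    """
    n_fam, rep_len = families.shape
    weights = np.exp(log_intensity - log_intensity.max())
    weights /= weights.sum()
    total_copies = coverage * seq.shape[0] / rep_len
    for f in range(n_fam):
        n_copies = rng.poisson(total_copies * weights[f])
        if n_copies == 0:
            continue
        starts = rng.integers(0, seq.shape[0] - rep_len, size=n_copies)
        for s in starts:
            seq[s : s + rep_len] = families[f]
    return seq


def generate_clade_genomes(spec: CladeSpec) -> CladeGenomes:
    """Sample clade-structured genomes; fully reproducible from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    n_ctx = 4 ** spec.markov_order
    base_logits = rng.normal(0.0, 1.0, size=(n_ctx, 4))
    families = _BASES[rng.integers(0, 4, size=(spec.n_repeat_families, spec.repeat_length))]
    base_intensity = rng.normal(0.0, 1.0, size=spec.n_repeat_families)
    genomes: list[GenomeSequence] = []
    clades: dict[str, int] = {}
    for c in range(spec.n_clades):
        clade_logits = base_logits + rng.normal(
            0.0, spec.clade_divergence, size=(n_ctx, 4)
        )
        clade_intensity = base_intensity + rng.normal(
            0.0, spec.clade_divergence, size=spec.n_repeat_families
        )
        for s in range(spec.species_per_clade):
            species_logits = clade_logits + rng.normal(
                0.0, spec.species_divergence, size=(n_ctx, 4)
            )
            species_intensity = clade_intensity + rng.normal(
                0.0, spec.species_divergence, size=spec.n_repeat_families
            )
            cum = np.cumsum(_softmax(species_logits), axis=1)
            cum[:, -1] = 1.0
            seq = _sample_chain(cum, spec.genome_length, spec.markov_order, rng)
            if spec.n_repeat_families and spec.repeat_coverage > 0:
                arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                arr = _plant_repeats(arr, families, species_intensity,
                                     spec.repeat_coverage, rng)
                seq = arr.tobytes().decode("ascii")
            label = f"clade{c + 1}_sp{s + 1}"
            genomes.append(GenomeSequence(label, _split_records(seq, rng)))
            clades[label] = c
    return CladeGenomes(genomes=genomes, clades=clades)


def expected_pairwise_identity(divergence: float, gap_rate: float = 0.0) -> float:
    """Closed-form expected identity between two simulated alignment rows.

    Each row mutates each ancestral site independently with probability d
    (to a uniformly chosen different base) and gaps it with probability g.
    Two rows agree at a mutation-eligible column when neither mutated or
    both mutated to the same base: p = (1-d)^2 + d^2/3. Both-gap columns
    are excluded from the denominator and gap-vs-letter counts as
    mismatch, giving E[identity] = (1-g) p / (1+g).
    """
    p_same = (1.0 - divergence) ** 2 + divergence ** 2 / 3.0
    return (1.0 - gap_rate) * p_same / (1.0 + gap_rate)


def generate_alignment(
    n_species: int,
    length: int,
    divergence: float,
    gap_rate: float = 0.0,
    seed: int = 0,
) -> AlignmentBlock:
    """Simulate a gapped alignment of ``n_species`` descendants of one ancestor.

    Per species and site: with probability ``divergence`` the ancestral
    base is replaced by a uniformly chosen different base; independently,
    with probability ``gap_rate`` the site is shown as a gap '-'.
    Reproducible from ``seed``.
    """
    if n_species < 2:
        raise InvalidParameterError("need at least 2 species")
    if length < 1:
        raise InvalidParameterError("length must be >= 1")
    if not 0.0 <= divergence < 1.0:
        raise InvalidParameterError(f"divergence must be in [0, 1), got {divergence}")
    if not 0.0 <= gap_rate < 0.5:
        raise InvalidParameterError(f"gap_rate must be in [0, 0.5), got {gap_rate}")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=length)
    rows = []
    for _ in range(n_species):
        bases = ancestor.copy()
        mut = rng.random(length) < divergence
        bases[mut] = (bases[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
        chars = _BASES[bases]
        gaps = rng.random(length) < gap_rate
        chars = np.where(gaps, np.uint8(ord("-")), chars)
        rows.append(chars.tobytes().decode("ascii"))
    labels = [f"sp{i + 1}" for i in range(n_species)]
    return AlignmentBlock(labels=labels, rows=rows)
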