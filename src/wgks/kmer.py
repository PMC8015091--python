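"""Whole-genome k-mer signature (WGKS) scoring.

A genome is reduced to a vector of per-k-mer scores

    S(w) = (O(w) - E(w)) / (O(w) + E(w))

where ``O`` is the observed overlapping occurrence count of the word ``w``
and ``E`` is a second-order Markov-style expectation built from the counts
of the word's two (k-1)-mers and its central (k-2)-mer:

    E(w) = O(w[0:k-1]) * O(w[1:k]) / O(w[1:k-1])

Scores lie in [-1, 1]: S -> 1 for over-represented words, S -> -1 for
under-represented words and S ~ 0 for words occurring at their expected
frequency. Because both O and E scale linearly with genome size the score
vector is invariant to (partial or complete) genome duplication, which is
what makes it usable as a whole-genome fingerprint across assemblies of
very different sizes and duplication histories.

Words are indexed in lexicographic order (AA...A to TT...T), i.e. by their
base-4 encoding with A=0, C=1, G=2, T=3, so the signature is a dense vector
of length 4**k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "GenomeSequence",
    "KmerCountTable",
    "ExpectedTable",
    "SignatureVector",
    "kmer_rank",
    "rank_to_kmer",
    "count_kmers",
    "expected_counts",
    "score_signature",
    "wgks_signature",
    "K_DEFAULT",
    "K_MIN",
    "K_MAX",
]

K_DEFAULT = 8   # octamers: 4**8 = 65,536 words
K_MIN = 3       # the expectation needs a non-empty middle word
K_MAX = 12      # dense 4**k vectors stay desk-scale up to here

_BASES = "ACGT"

# byte -> 2-bit code; -1 marks any non-ACGT letter (N, IUPAC codes, ...)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class GenomeSequence:
    """One species' assembly: an ordered collection of DNA records.

    Records are scaffolds/contigs; k-mer windows never cross record
    boundaries. Input letters are normalized to uppercase; anything outside
    {A, C, G, T} is kept verbatim and treated as an ambiguous position by
    the counter.
    """

    species_label: str
    records: tuple[str, ...]

    def __init__(self, species_label: str, records):
        records = tuple(str(r).upper() for r in records)
        if not species_label:
            raise InvalidInputError("species_label must be a non-empty string")
        if not records:
            raise InvalidInputError(f"{species_label}: genome has no records")
        if any(len(r) == 0 for r in records):
            raise InvalidInputError(f"{species_label}: empty record in genome")
        object.__setattr__(self, "species_label", str(species_label))
        object.__setattr__(self, "records", records)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    def duplicated(self) -> "GenomeSequence":
        """Return a genome with every record appearing twice (same label)."""
        return GenomeSequence(self.species_label, self.records + self.records)


@dataclass(frozen=True)
class KmerCountTable:
    """Observed occurrences O of all 4**k words, lexicographic order."""

    k: int
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if self.k < 1:
            raise InvalidParameterError(f"k must be >= 1, got {self.k}")
        if counts.shape != (4 ** self.k,):
            raise InvalidInputError(
                f"count table for k={self.k} must have length {4 ** self.k}, "
                f"got {counts.shape}"
            )
        if (counts < 0).any():
            raise InvalidInputError("k-mer counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, word: str) -> int:
        return int(self.counts[kmer_rank(word)])


@dataclass(frozen=True)
class ExpectedTable:
    """Expected occurrences E of all 4**k words, lexicographic order."""

    k: int
    expected: np.ndarray = field(repr=False)

    def __post_init__(self):
        expected = np.asarray(self.expected, dtype=np.float64)
        if expected.shape != (4 ** self.k,):
            raise InvalidInputError(
                f"expected table for k={self.k} must have length {4 ** self.k}"
            )
        if not np.isfinite(expected).all() or (expected < 0).any():
            raise InvalidInputError("expected counts must be finite and >= 0")
        object.__setattr__(self, "expected", expected)

    def __getitem__(self, word: str) -> float:
        return float(self.expected[kmer_rank(word)])


@dataclass(frozen=True)
class SignatureVector:
    """The WGKS fingerprint: scores for all 4**k words in lexicographic order."""

    species_label: str
    k: int
    scores: np.ndarray = field(repr=False)

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=np.float64)
        if scores.shape != (4 ** self.k,):
            raise InvalidInputError(
                f"signature for k={self.k} must have length {4 ** self.k}"
            )
        if (np.abs(scores) > 1.0 + 1e-12).any():
            raise InvalidInputError("signature scores must lie in [-1, 1]")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return self.scores.shape[0]

    def __getitem__(self, word: str) -> float:
        return float(self.scores[kmer_rank(word)])


def kmer_rank(word: str) -> int:
    """Lexicographic rank of a word: its base-4 value with A=0,C=1,G=2,T=3."""
    rank = 0
    for ch in word.upper():
        code = _BASES.find(ch)
        if code < 0:
            raise InvalidParameterError(f"non-ACGT letter {ch!r} in word {word!r}")
        rank = rank * 4 + code
    if not word:
        raise InvalidParameterError("empty word has no rank")
    return rank


def rank_to_kmer(rank: int, k: int) -> str:
    """Inverse of :func:`kmer_rank` for words of length k."""
    if not 0 <= rank < 4 ** k:
        raise InvalidParameterError(f"rank {rank} out of range for k={k}")
    letters = []
    for _ in range(k):
        letters.append(_BASES[rank & 3])
        rank >>= 2
    return "".join(reversed(letters))


def _record_ranks(record: str, k: int) -> np.ndarray:
    """Ranks of all valid (all-ACGT) length-k windows of one record."""
    codes = _CODE[np.frombuffer(record.encode("ascii", "replace"), dtype=np.uint8)]
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    n_win = n - k + 1
    bad = np.concatenate(([0], np.cumsum(codes < 0)))
    valid = (bad[k:] - bad[:-k]) == 0
    clipped = np.where(codes < 0, 0, codes).astype(np.int64)
    ranks = np.zeros(n_win, dtype=np.int64)
    for j in range(k):
        ranks = ranks * 4 + clipped[j : j + n_win]
    return ranks[valid]


def count_kmers(genome: GenomeSequence, k: int, canonical: bool = False) -> KmerCountTable:
    """Count overlapping k-mer occurrences in a genome.

    Every window of length k whose letters are all in {A,C,G,T} contributes
    one count to its word; windows containing any other letter (N runs and
    IUPAC ambiguity codes in real assemblies) are skipped entirely, and
    windows never span record boundaries.

    Parameters
    ----------
    genome : GenomeSequence
    k : int
        Word length, >= 1 and no longer than the longest record.
    canonical : bool, default False
        If True, additionally count the reverse-complement strand (every
        window contributes to both its own word and its reverse
        complement). The default counts the forward strand only.
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    if k > max(len(r) for r in genome.records):
        raise InvalidParameterError(
            f"k={k} exceeds the longest record ({max(len(r) for r in genome.records)} bp) "
            f"of {genome.species_label}"
        )
    counts = np.zeros(4 ** k, dtype=np.int64)
    for record in genome.records:
        ranks = _record_ranks(record, k)
        counts += np.bincount(ranks, minlength=4 ** k)
        if canonical:
            rc = record.translate(_COMPLEMENT)[::-1]
            counts += np.bincount(_record_ranks(rc, k), minlength=4 ** k)
    return KmerCountTable(k=k, counts=counts)


def expected_counts(o_k1: KmerCountTable, o_k2: KmerCountTable, k: int) -> ExpectedTable:
    """Markov expectation E(w) = O(prefix) * O(suffix) / O(middle) for all words.

    ``prefix``/``suffix`` are w's two (k-1)-mers and ``middle`` its central
    (k-2)-mer. Words whose middle count is zero get E = 0 (the prefix and
    suffix counts are then necessarily zero too, since every prefix/suffix
    occurrence contains a middle occurrence).
    """
    if k < 3:
        raise InvalidParameterError(f"the expectation needs k >= 3, got k={k}")
    if o_k1.k != k - 1 or o_k2.k != k - 2:
        raise InvalidParameterError(
            f"need count tables at k-1={k - 1} and k-2={k - 2}, "
            f"got {o_k1.k} and {o_k2.k}"
        )
    idx = np.arange(4 ** k, dtype=np.int64)
    prefix = idx >> 2                      # drop last letter
    suffix = idx & (4 ** (k - 1) - 1)      # drop first letter
    middle = prefix & (4 ** (k - 2) - 1)   # drop first and last letters
    o_pre = o_k1.counts[prefix].astype(np.float64)
    o_suf = o_k1.counts[suffix].astype(np.float64)
    o_mid = o_k2.counts[middle].astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.where(o_mid > 0, o_pre * o_suf / np.where(o_mid > 0, o_mid, 1.0), 0.0)
    return ExpectedTable(k=k, expected=expected)


def score_signature(
    observed: KmerCountTable, expected: ExpectedTable, species_label: str = ""
) -> SignatureVector:
    """Score S(w) = (O - E) / (O + E) per word; S = 0 where O = E = 0.

    The 0/0 completion assigns the neutral "randomly occurring" value to
    words absent from the genome and predicted absent, which is the only
    finite symmetric completion of the score.
    """
    if observed.k != expected.k:
        raise InvalidParameterError(
            f"observed (k={observed.k}) and expected (k={expected.k}) word lengths differ"
        )
    o = observed.counts.astype(np.float64)
    e = expected.expected
    denom = o + e
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(denom > 0, (o - e) / np.where(denom > 0, denom, 1.0), 0.0)
    return SignatureVector(species_label=species_label, k=observed.k, scores=scores)


def wgks_signature(genome: GenomeSequence, k: int = K_DEFAULT, canonical: bool = False) -> SignatureVector:
    """Full signature pipeline for one genome: counts at k, k-1, k-2 -> scores."""
    if not K_MIN <= k <= K_MAX:
        raise InvalidParameterError(f"k must be in [{K_MIN}, {K_MAX}], got {k}")
    o_k = count_kmers(genome, k, canonical=canonical)
    o_k1 = count_kmers(genome, k - 1, canonical=canonical)
    o_k2 = count_kmers(genome, k - 2, canonical=canonical)
    expected = expected_counts(o_k1, o_k2, k)
    return score_signature(o_k, expected, species_label=genome.species_label)
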