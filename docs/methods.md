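# Methods

## The signature model

A genome is modelled as a bag of overlapping words. For word length k
the observed count O(w) is compared with the Markov-style expectation
E(w) = O(prefix)·O(suffix)/O(middle), where prefix and suffix are w's
two (k−1)-mers and middle its central (k−2)-mer. E is exactly the
plug-in estimate of L·P(w) under a Markov chain of order k−2 fitted to
the genome itself; the score S = (O−E)/(O+E) therefore measures
*residual* word preference beyond everything order-(k−2) composition
explains. Three consequences shape everything downstream:

- **Scale invariance.** O and E scale together with genome length, so S
  is invariant to (partial) duplication. The tests require the
  invariance to hold to 1e−12 per entry, and it holds exactly because
  windows never cross record boundaries (appending copied records
  exactly doubles every count).
- **Range and degenerate cases.** S ∈ [−1, 1] always; S = +1 iff E = 0 < O,
  S = −1 iff O = 0 < E. When O = E = 0 the score is defined as 0, the
  neutral "occurring as expected" value — the only finite symmetric
  completion. Words whose middle (k−2)-mer count is zero get E = 0.
- **Blindness to low-order structure.** Any genome whose statistics are
  fully captured by a Markov chain of order ≤ k−2 has S ≈ 0 everywhere
  up to sampling noise. The signature sees long-range word structure:
  repeats, mobile-element families, conserved motifs. This is a design
  feature of the statistic, and it dictated the design of the synthetic
  generator (below).

Counting uses a rolling 2-bit encoding with a dense 4^k vector; windows
containing any non-ACGT letter are skipped whole (assemblies contain N
runs; any partial-window convention would invent counts). Only the
forward strand is counted by default, matching the single-strand
definition of the score; a `canonical=True` mode adds the
reverse-complement strand and is documented as a deviation. k is
configurable in [3, 12] (k = 8, 65,536 words, is the default; 4^12 ≈
1.7e7 doubles ≈ 130 MB is the practical dense-vector ceiling).

## Species comparison and clustering

Signatures are compared by Pearson correlation over the full 4^k
vector, with zero-variance signatures rejected explicitly rather than
propagated as NaN. Clustering operates on d = 1 − similarity:

- **Hopkins statistic** (clustering tendency): matrix rows are points in
  R^n; m = max(3, ⌈0.1·n⌉) sampled points and m uniform reference
  points in the per-dimension bounding box; H = Σu/(Σu+Σw). The
  fraction, box convention and seed are explicit parameters because the
  statistic has no single canonical parametrization.
- **Cluster number**: average silhouette width (precomputed distances)
  and the within-cluster sum-of-squares elbow, swept over 2–7 clusters
  by default.
- **Cluster extraction**: cut of the agglomerative tree (SciPy linkage;
  Ward for genome studies, single linkage for the identity stage,
  average = UPGMA always available). k-means and PAM are provided as
  seeded alternative extractors, not used in the main path.
- **Cluster statistics**: per cluster, min/mean/max/sd of within-cluster
  pairwise similarity. sd needs ≥ 3 members and is reported missing
  below that, as are all summaries for singletons.
- **Significance**: one-sided test of within-cluster pairs against pairs
  straddling the boundary. Welch's t is the default — pair sets are
  large and the astronomically small p-values such comparisons produce
  are characteristic of t-statistics — with Mann–Whitney U as the
  nonparametric guard. p-values are floored at the smallest positive
  double so that "p ∈ (0, 1]" holds literally. The pairs within one
  cluster share species and are therefore not independent; the reported
  p-values are descriptive strength-of-separation measures, calibrated
  only under full exchangeability (which the null-calibration test
  verifies by KS uniformity over 200 simulated matrices).

## Trees

UPGMA and neighbor joining are implemented directly (O(n³), fine for
dozens of species) with deterministic tie-breaking by smallest member
label, so permuting the input permutes leaves without changing
topology. UPGMA output is ultrametric by construction; NJ reconstructs
additive matrices exactly (both verified against SciPy's cophenetic
distances and scikit-bio's NJ in the tests, which keeps implementation
and oracle separate). Negative NJ branch lengths — possible on
non-additive input — are clamped to zero with the deficit moved to the
sister branch, preserving the pair's total. Newick output quotes labels
containing reserved characters; parsing is delegated to scikit-bio.

## The synthetic generator

`generate_clade_genomes` plants a known clade structure with two
layers:

1. a base order-m Markov chain (default m = 2) perturbed in logit space
   per clade (σ = `clade_divergence`) and per species
   (σ = `species_divergence` < clade divergence), from which each
   genome's background is sampled and split into 2–5 records;
2. a pool of repeat/motif families — random words drawn once per
   simulation (default 40 families × 150 bp) — planted to ~35% genome
   coverage, with per-family log-intensities perturbed per clade and
   per species at the same two scales.

The second layer exists because of the signature's blindness to
low-order structure: a background chain of order ≤ k−2 is cancelled
from the signature by construction, so clade identity must live in
long-range word structure for the pipeline to have anything to detect.
Interspersed repeat families are exactly that structure in real
genomes — mammalian assemblies are 40–50% interspersed repeats in
strongly lineage-specific subfamilies — and family intensity is the
natural clade-level dial. The defaults (coverage, family count and
length, divergence scales) were fixed from that analogy.

What passing tests on this generator show: the pipeline recovers
composition-based clade structure of realistic strength from realistic
genome sizes, with correctly ordered within/between similarities and
well-calibrated significance under the null. What they do not show:
robustness to assembly artifacts, uneven genome sizes spanning orders
of magnitude, base-composition convergence between unrelated lineages,
or any property of real repeat biology (decay, insertion preference,
indels) — the generator has none of those.

`generate_alignment` mutates an ancestral sequence i.i.d. per species
and site (probability d, uniform choice among the three other bases)
and gaps sites i.i.d. (probability g). Two rows then agree at a
counted column with probability (1−d)² + d²/3, and with both-gap
columns excluded and gap-vs-letter counted as mismatch the expected
identity is (1−g)·[(1−d)² + d²/3]/(1+g) — the closed form the identity
tests check against (0.8133 at d = 0.1, g = 0).

## Identity counting dialects

Alignment viewers disagree on gap and ambiguity handling, so the
conventions are explicit and switchable: both-gap columns excluded from
the denominator (or counted as matches), gap-vs-letter a mismatch (or
excluded), non-ACGT letters match nothing (or match when equal). The
defaults are the strictest reading; all three switches are exposed in
the API and CLI so alternative dialects can be compared directly.

## Numerical choices and problem sizes

- Correlations and scores in double precision over the full vector; no
  filtering of zero-score entries.
- Matrix containers enforce symmetry to 1e−12, exact unit diagonal and
  range, then re-symmetrize and clip to kill float drift.
- UPGMA/NJ tie-breaks by label order; ultrametricity asserted to 1e−9.
- Test and acceptance runs use genomes of 20–500 kb at k ∈ {3..8} and
  12-species studies — sizes chosen so the full suite exercises every
  stage, including the 200 kb × 12 planted-clade study, in well under a
  minute of compute per stage. The implementation itself is
  desk-scale: a 2.5 Gb mammalian assembly at k = 8 is a few minutes of
  counting per species in pure NumPy.

## Known limitations

- Dense 4^k vectors cap k at 12; no minimizer or disk-backed counting.
- The cluster p-values are descriptive (pair dependence, see above).
- NJ consumes a distance matrix only; maximum-likelihood trees and
  bootstrap support are out of scope, as is computing alignments.
- Hopkins on n points in n dimensions (rows of the similarity matrix)
  is conservative for small n; its value depends on the
  rows-as-points convention, which is stated in the output metadata.
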