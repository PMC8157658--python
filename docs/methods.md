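# Methods

## Problem setting

The package takes (i) one or more *target* sets of CpG sites, each labelled
hyper- or hypo-methylated in a condition of interest, (ii) a *background*
set representing the universe of tested CpGs, (iii) a reference genome and
a CpG annotation mapping probe IDs to genomic coordinates, and (iv) a PWM
database of known transcription-factor motifs. It reports IUPAC consensus
motifs enriched in the target flanking sequences, their methylation trend,
their mutual similarity structure, and their resemblance to known TF
binding models.

## Coordinates and flank extraction

Annotation positions are 1-based and denote the C of the CpG dinucleotide
(the methylation-array manifest convention); internal intervals are 0-based
half-open. The flank of size *w* is the 1-based inclusive window
[p − w, p + 1 + w]: *w* bases upstream of the C through *w* bases
downstream of the G, total length 2*w* + 2 (the default *w* = 20 gives
42-bp windows). Windows overrunning a contig end are truncated and logged.
Flanks are always reported on the forward reference strand — the motif
scan is strand-aware downstream, so extracting reverse-strand flanks would
only duplicate work. A flank whose centre is not `CG` triggers a warning
rather than an error, so non-CpG cytosine contexts remain usable.

## Discovery statistic

Counting is at the *sequence* level: a word is either present in a flank
(on either strand) or not, so presence counts over n₊ target and n₋
background flanks form a 2×2 table with fixed margins and the Fisher exact
test applies. `fisher_exact_2x2` is implemented with exact integer
arithmetic: point probabilities are integer weights
w(x) = C(r₁, x)·C(n − r₁, c₁ − x) over a common denominator, the one-sided
(greater) p is the upper tail, and the two-sided p sums all tables whose
weight is ≤ the observed weight — the tie rule is decided on integers, so
there is no floating-point ambiguity. The vectorized
`scipy.stats.hypergeom.sf` computes the same upper tail inside the hot
enumeration loop; `scipy.stats.fisher_exact` serves as an independent
cross-check in the tests, never as the implementation.

An all-zero table is defined to have p = 1 (with a warning): no data is no
evidence.

## Discovery loop

Per round:

1. every exact ACGT word of length k ∈ [k_min, k_max] (defaults 3, 8)
   present in the positive flanks — windows containing N are skipped — is
   scored by the one-sided Fisher p; ties prefer the longer, then
   lexicographically smaller word;
2. the best word seeds a greedy beam search (width 8): each step proposes
   all single-position replacements by a *strictly more permissive* IUPAC
   code, keeps the beam-width best by p, and stops when no proposal
   improves on the best p seen, which guarantees the returned word's p
   never exceeds the seed's and that the search terminates;
3. E = p × n_candidates, where n_candidates counts the distinct words
   scored in this round (exact enumeration plus generalization proposals;
   per-round rather than cumulative counting was chosen so the multiplier
   reflects the search that produced the motif). E is deliberately not
   clamped to 1;
4. if p or E exceeds its threshold (defaults 0.05 / 0.05) the loop stops;
   otherwise the motif is recorded and every matched window, on both
   strands, is erased to N in positives and negatives. Erased bases match
   no concrete IUPAC code (N in a sequence matches only the wildcard code
   N), so later rounds cannot rediscover the same signal.

The erasure rule follows the operation's contract — all matched windows on
both strands are replaced — so a word whose reverse complement also occurs
in a sequence erases both occurrences.

Sequence-level counting, one-sided testing (only over-representation in
targets is of interest), erasure and the IUPAC generalization follow the
standard discriminative word-discovery scheme; the beam proposal set
(single-code strict supersets) and the deterministic tie-breaks are this
package's own choices, made so that outputs are reproducible bit-for-bit.

## Methylation unbalance

For each motif the supporting set (target CpGs whose flank contains the
consensus, either strand) is tested against the universe with a two-sided
Fisher test on [[hyper_support, hypo_support], [hyper_universe,
hypo_universe]]. The universe defaults to the full target set, which is
always status-labelled; the background file carries no methylation calls,
so using it would require imputation. A labelled custom universe can be
supplied instead. The methylation ratio is n_hyper/n_hypo, serialized as
the literal `Inf` when n_hypo = 0. Trend: the majority fraction must reach
the unbalance threshold (default 0.7) *and* the unbalance p must pass its
threshold; the default p-threshold of 1.0 makes the p-filter inert, so by
default classification is purely by majority.

## Consensus similarity and clustering

Two IUPAC codes score |bases(x) ∩ bases(y)| / (|bases(x)|·|bases(y)|) —
the probability that bases drawn uniformly from each code coincide
(A:A = 1, W:W = 0.5, N:N = 0.25, disjoint = 0). Consensus strings are
aligned globally (Needleman–Wunsch with affine gaps, cost
open + k·extend, defaults 10/4, via Biopython's `PairwiseAligner` with a
custom 15-letter matrix). Pairwise scores are min-max normalized over the
off-diagonal pairs and distance = 1 − normalized score; the diagonal is
forced to 0 because self-scores grow with motif length and would otherwise
break the zero-diagonal contract. When all pairs score identically the
distances are all set to 0 with a warning — equal evidence of similarity
should not fabricate separation; note this makes any two-motif matrix
degenerate by construction.

Clustering is agglomerative with average linkage by default (UPGMA over
the original leaf-pair distances; complete and single are exposed as
flags). Node height is merge distance / 2, giving an ultrametric tree; all
three linkages satisfy reducibility, so heights never invert. Ties in the
minimal distance are broken by the lexicographically smallest pair of
cluster representatives (each cluster represented by its smallest leaf
label) and children are written smallest-representative first, making the
Newick output deterministic. Leaf labels carry the methylation trend as a
`|trend` suffix.

## PWM matching

A consensus becomes a query PFM by spreading each code uniformly over its
bases (`--pfm-source occurrences` instead estimates columns from the
motif's actual occurrences in the flanks with add-0.25 pseudocounts).
Column similarity is 1 − ‖p − q‖₂/√2, which is defined for every pair of
probability columns — including uniform ones, where correlation-based
scores degenerate. The query slides ungapped across each database PFM in
both orientations (reverse complement = reversed columns with A↔T, C↔G
swapped); the reported configuration maximizes the mean column score over
the overlap, with ties preferring the smaller |offset|, then '+'.

Significance is Monte-Carlo: n_null (default 1000) column-shuffled copies
of the target are rescored with the same search, and
p = (1 + #{null > observed}) / (1 + n_null) — the add-one estimator, so p
∈ [1/(1+n_null), 1] and identical seeds give identical results (each
target gets its own seeded stream, so results are independent of database
order). Nulls are counted when they **strictly** exceed the observed
score: the shuffle preserves the target's column multiset, so a perfect
query–target match is re-attained exactly by any shuffle through a short
overlap against one identical column; counting those ties would make
perfect matches maximally insignificant. For continuous columns exact
ties have probability zero and strict/non-strict counting coincide.
E = p × database size; q-values are Benjamini–Hochberg (statsmodels) over
the per-database p-values; matches must pass all four thresholds
(defaults p ≤ 0.05, E ≤ 10, q ≤ 1, overlap ≥ 1).

## Synthetic data

The generator emulates the input formats end to end: i.i.d. genome at 41%
GC (human-like), CpGs on a regular grid (stride 2w + 4) so flanks are
pairwise disjoint and never cross contig ends, `CG` written at every
annotated position. Planting is deterministic in count — round(f·n) flanks
per set, chosen by a seeded permutation — so fixtures are exactly
assertable; each planted flank receives one realization of the IUPAC word
(ambiguous positions sampled uniformly) at a seeded offset that never
overwrites the central CG. Default conditions: 300 target / 300 background
CpGs, w = 20, word `TGAWAAA` at 40% target vs 2% background frequency,
hyper-methylation probability 0.9 for planted vs 0.5 for unplanted
targets. The PFM database is 10 random Dirichlet(0.7)-column motifs of
width 5–12, plus an embedded PFM of the planted word as a positive
control.

What the generator does *not* emulate: CpG islands and regional CpG
density, beta-value distributions and calling noise, probe biases, strand
asymmetries, repeat structure. Passing tests therefore demonstrate that
the statistics and the search behave correctly under their stated
assumptions — not that motifs recovered from real arrays are biologically
meaningful, which additionally depends on the quality of the
differential-methylation calls and the annotation.

## Numerical and interface choices

- All randomness (simulation, Monte-Carlo null) flows from integer seeds
  through independent `numpy` generator streams; discovery itself is
  deterministic, with explicit tie-breaks everywhere a tie is possible.
- Motif p/E thresholds are conjunctive; every threshold filter is monotone
  (tightening never adds rows), which the tests verify.
- PFM columns must sum to 1 within 1e-6; the writer emits 8 decimals so
  files round-trip within tolerance.
- Degenerate inputs: empty motif list short-circuits clustering/TFBS with
  header-only outputs and exit code 0; an empty supporting set is a hard
  error naming the motif; unsatisfiable PWM overlap returns a "no valid
  alignment" sentinel rather than a score.
- Problem sizes used by the test-suite and the acceptance script (full
  Fisher sweep at N ≤ 25; 10 discovery seeds at 300/300; 20 null seeds at
  200/200; n_null = 1000) complete in about a minute on one CPU.

## Known limitations

- Discovery is ungapped and word-based; PWM-style (EM/Gibbs) discovery and
  gapped motifs are out of scope.
- The E-value multiplier counts candidates per round, so E-values across
  rounds are not jointly corrected.
- Clustering operates on consensus strings, not on occurrence matrices;
  motifs with similar consensus but different information content are not
  distinguished.
- The Monte-Carlo PWM p-value resolution is 1/(1+n_null); q-values inherit
  that granularity.
- Illumina 450K/EPIC manifests are not parsed natively; convert them to
  the generic annotation TSV (`cpg_id  chrom  pos  [strand]`).
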