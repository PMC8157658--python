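"""Discriminative de novo motif discovery on target vs background flanks.

The algorithm follows the classic discriminative word-enumeration scheme:

1. every exact word of length ``k_min..k_max`` present in the positive
   (target) sequences — on either strand — is scored with a one-sided
   Fisher exact test on the 2x2 table of sequence-level presence counts
   (positives vs negatives, with vs without the word);
2. the best exact word seeds a greedy beam search that generalizes one
   position at a time to a strictly more permissive IUPAC code, accepted
   only while the Fisher p-value improves;
3. the motif's E-value is its p-value times the number of distinct
   candidate words scored in that round; motifs passing both the p and E
   thresholds are recorded, their occurrences erased (matched bases
   replaced by N on both strands) and the loop repeats on the erased
   sequences, so successive motifs describe disjoint signal.

Counts are at the sequence level (a sequence carrying five occurrences
counts once), which makes the 2x2 margins fixed and the Fisher test
applicable.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .iupac import (
    STRICT_SUPERSETS,
    contains_word,
    match_positions,
    revcomp,
    validate_word,
    word_pattern,
)

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryParams:
    """Knobs of the discovery loop.

    ``k_min``/``k_max`` bound the exact seed-word length; ``p_threshold``
    and ``e_threshold`` are conjunctive significance filters on the
    reported motifs; ``beam_width`` controls the IUPAC generalization
    beam.  ``seed`` is carried for interface uniformity — the search
    itself is fully deterministic.
    """

    k_min: int = 3
    k_max: int = 8
    p_threshold: float = 0.05
    e_threshold: float = 0.05
    max_motifs: int = 10
    beam_width: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError(f"need 1 <= k_min <= k_max, got ({self.k_min}, {self.k_max})")
        if not (0 < self.p_threshold <= 1):
            raise ValueError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if self.e_threshold <= 0:
            raise ValueError(f"e_threshold must be > 0, got {self.e_threshold}")
        if self.beam_width < 1:
            raise ValueError(f"beam_width must be >= 1, got {self.beam_width}")


@dataclass
class Motif:
    """A discovered motif with its enrichment evidence."""

    consensus: str
    pvalue: float
    evalue: float
    n_pos_with: int
    n_pos_without: int
    n_neg_with: int
    n_neg_without: int
    supporting_cpgs: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.consensus)


def fisher_exact_2x2(a: int, b: int, c: int, d: int, alternative: str = "greater") -> float:
    """Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    Computed with exact integer arithmetic.  ``greater`` is the upper
    hypergeometric tail P(X >= a) with row/column margins fixed;
    ``two_sided`` sums every table with the same margins whose point
    probability is at most that of the observed table (the tie rule is
    decided on exact integer weights, so there is no floating-point
    ambiguity).  An all-zero table returns 1.0 with a warning.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"alternative must be 'greater' or 'two_sided', got {alternative!r}")
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or v != int(v):
            raise ValueError(f"count {name} must be a non-negative integer, got {v}")
    if a == b == c == d == 0:
        warnings.warn("all-zero 2x2 table: p-value set to 1.0", stacklevel=2)
        return 1.0
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    # integer weights w(x) = C(r1, x) * C(n - r1, c1 - x); denominator C(n, c1)
    weights = {x: math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(lo, hi + 1)}
    total = math.comb(n, c1)
    if alternative == "greater":
        num = sum(w for x, w in weights.items() if x >= a)
    else:
        w_obs = weights[a]
        num = sum(w for w in weights.values() if w <= w_obs)
    return num / total


def evalue(pvalue: float, n_candidates: int) -> float:
    """Motif E-value: p-value times the number of candidate motifs tested."""
    if not (0 <= pvalue <= 1):
        raise ValueError(f"pvalue must be in [0, 1], got {pvalue}")
    if n_candidates < 1:
        raise ValueError(f"n_candidates must be >= 1, got {n_candidates}")
    return pvalue * n_candidates  # deliberately not clamped to 1


def count_sequences_with_word(word: str, seqs: Iterable[str], both_strands: bool = True) -> int:
    """Number of sequences containing the word at least once (not occurrences)."""
    validate_word(word)
    return sum(1 for s in seqs if contains_word(s, word, both_strands))


def erase_occurrences(seqs: Sequence[str], word: str) -> list[str]:
    """Replace every base covered by a match of ``word`` (either strand) by N."""
    validate_word(word)
    out: list[str] = []
    for s in seqs:
        covered = match_positions(s, word, both_strands=True)
        if covered:
            s = "".join("N" if i in covered else ch for i, ch in enumerate(s))
        out.append(s)
    return out


def _present_word_sets(seq: str, k_min: int, k_max: int) -> set[str]:
    """Exact ACGT words (either strand) present in one sequence."""
    words: set[str] = set()
    for s in (seq, revcomp(seq)):
        n = len(s)
        for k in range(k_min, min(k_max, n) + 1):
            for i in range(n - k + 1):
                w = s[i:i + k]
                if "N" not in w:
                    words.add(w)
    return words


def _count_words(seqs: Sequence[str], k_min: int, k_max: int) -> Counter:
    counts: Counter = Counter()
    for s in seqs:
        counts.update(_present_word_sets(s, k_min, k_max))
    return counts


def _one_sided_p(a, c, n_pos: int, n_neg: int):
    """Vectorized upper-tail hypergeometric p: P(X >= a) with margins fixed."""
    a = np.asarray(a)
    c = np.asarray(c)
    return hypergeom.sf(a - 1, n_pos + n_neg, a + c, n_pos)


def _best_exact_word(pos_seqs: Sequence[str], neg_seqs: Sequence[str],
                     params: DiscoveryParams) -> tuple[str | None, float, int]:
    """Best (lowest-p) exact word in the positives; returns (word, p, n_words)."""
    pos_counts = _count_words(pos_seqs, params.k_min, params.k_max)
    if not pos_counts:
        return None, 1.0, 0
    neg_counts = _count_words(neg_seqs, params.k_min, params.k_max)
    words = list(pos_counts)
    a = np.fromiter((pos_counts[w] for w in words), dtype=np.int64, count=len(words))
    c = np.fromiter((neg_counts.get(w, 0) for w in words), dtype=np.int64, count=len(words))
    p = _one_sided_p(a, c, len(pos_seqs), len(neg_seqs))
    # ties: longer word first, then lexicographic
    best_i = min(range(len(words)), key=lambda i: (p[i], -len(words[i]), words[i]))
    return words[best_i], float(p[best_i]), len(words)


def generalize_word(
    seed_word: str,
    pos_seqs: Sequence[str],
    neg_seqs: Sequence[str],
    beam_width: int = 8,
) -> tuple[str, float, int]:
    """Greedy beam generalization of an exact seed word to an IUPAC word.

    Each step proposes every single-position replacement of a beam word
    by a strictly more permissive IUPAC code, scores the proposals by the
    one-sided Fisher p, and stops when no proposal improves on the best
    p seen so far.  Returns ``(best_word, best_p, n_words_evaluated)``;
    the best word may be the seed itself, and its p-value never exceeds
    the seed's.
    """
    if beam_width < 1:
        raise ValueError(f"beam_width must be >= 1, got {beam_width}")
    validate_word(seed_word)
    if any(ch not in "ACGT" for ch in seed_word):
        raise ValueError(f"seed word must be an exact ACGT word, got {seed_word!r}")
    n_pos, n_neg = len(pos_seqs), len(neg_seqs)

    def score(word: str) -> float:
        a = count_sequences_with_word(word, pos_seqs)
        c = count_sequences_with_word(word, neg_seqs)
        return float(_one_sided_p(a, c, n_pos, n_neg))

    evaluated: dict[str, float] = {seed_word: score(seed_word)}
    best_word, best_p = seed_word, evaluated[seed_word]
    beam = [seed_word]
    while True:
        proposals: dict[str, float] = {}
        for w in beam:
            for i, code in enumerate(w):
                for sup in STRICT_SUPERSETS[code]:
                    cand = w[:i] + sup + w[i + 1:]
                    if cand not in evaluated:
                        p = score(cand)
                        evaluated[cand] = p
                        proposals[cand] = p
        if not proposals:
            break
        ranked = sorted(proposals.items(), key=lambda kv: (kv[1], kv[0]))
        if ranked[0][1] >= best_p:
            break
        best_word, best_p = ranked[0]
        beam = [w for w, _ in ranked[:beam_width]]
    return best_word, best_p, len(evaluated)


def discover_motifs(
    pos_seqs: Sequence[str],
    neg_seqs: Sequence[str],
    params: DiscoveryParams | None = None,
    pos_ids: Sequence[str] | None = None,
) -> list[Motif]:
    """Iterative discovery of enriched motifs with erasure between rounds.

    ``pos_ids`` (optional, same order as ``pos_seqs``) populates each
    motif's supporting CpG list.  The output is sorted by ascending
    p-value, ties broken by longer consensus then lexicographic order;
    every reported motif satisfies both the p and E thresholds.
    """
    params = params or DiscoveryParams()
    pos = [s.upper() for s in pos_seqs]
    neg = [s.upper() for s in neg_seqs]
    if not pos or not neg:
        raise ValueError("both the positive and the negative sequence set must be non-empty")
    if pos_ids is not None and len(pos_ids) != len(pos):
        raise ValueError("pos_ids must parallel pos_seqs")
    ids = list(pos_ids) if pos_ids is not None else [f"seq{i + 1}" for i in range(len(pos))]

    motifs: list[Motif] = []
    round_no = 0
    while len(motifs) < params.max_motifs:
        round_no += 1
        seed_word, seed_p, n_exact = _best_exact_word(pos, neg, params)
        if seed_word is None:
            logger.info("round %d: no candidate words left; stopping", round_no)
            break
        word, p, n_gen = generalize_word(seed_word, pos, neg, params.beam_width)
        n_candidates = n_exact + n_gen - 1  # the seed word is in both pools
        e = evalue(p, n_candidates)
        logger.info(
            "round %d: best word %s (seed %s, p=%.3g, E=%.3g over %d candidates)",
            round_no, word, seed_word, p, e, n_candidates,
        )
        if p > params.p_threshold or e > params.e_threshold:
            break
        a = count_sequences_with_word(word, pos)
        c = count_sequences_with_word(word, neg)
        supporting = [i for i, s in zip(ids, pos) if contains_word(s, word)]
        motifs.append(
            Motif(
                consensus=word,
                pvalue=p,
                evalue=e,
                n_pos_with=a,
                n_pos_without=len(pos) - a,
                n_neg_with=c,
                n_neg_without=len(neg) - c,
                supporting_cpgs=supporting,
            )
        )
        pos = erase_occurrences(pos, word)
        neg = erase_occurrences(neg, word)
    motifs.sort(key=lambda m: (m.pvalue, -m.length, m.consensus))
    return motifs


# --- motif table serialization (TSV contract of the discover subcommand) ---

MOTIF_TSV_COLUMNS = (
    "consensus", "length", "pvalue", "evalue",
    "n_pos_with", "n_pos_without", "n_neg_with", "n_neg_without",
    "supporting_cpgs",
)


def write_motif_tsv(motifs: Sequence[Motif], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MOTIF_TSV_COLUMNS) + "\n")
        for m in motifs:
            fh.write(
                "\t".join(
                    [
                        m.consensus,
                        str(m.length),
                        repr(m.pvalue),
                        repr(m.evalue),
                        str(m.n_pos_with),
                        str(m.n_pos_without),
                        str(m.n_neg_with),
                        str(m.n_neg_without),
                        ";".join(m.supporting_cpgs),
                    ]
                )
                + "\n"
            )


def read_motif_tsv(path) -> list[Motif]:
    motifs: list[Motif] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: header.index(c) for c in header}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            supporting = f[idx["supporting_cpgs"]] if "supporting_cpgs" in idx else ""
            motifs.append(
                Motif(
                    consensus=f[idx["consensus"]],
                    pvalue=float(f[idx["pvalue"]]),
                    evalue=float(f[idx["evalue"]]),
                    n_pos_with=int(f[idx["n_pos_with"]]),
                    n_pos_without=int(f[idx["n_pos_without"]]),
                    n_neg_with=int(f[idx["n_neg_with"]]),
                    n_neg_without=int(f[idx["n_neg_without"]]),
                    supporting_cpgs=supporting.split(";") if supporting else [],
                )
            )
    return motifs
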