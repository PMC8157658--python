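"""IUPAC nucleotide ambiguity codes and strand-aware word matching.

Every motif consensus in this package is a string over the 15-letter IUPAC
alphabet (A, C, G, T plus the 11 ambiguity codes).  Genomic sequences are
strings over {A, C, G, T, N}.  Matching is asymmetric on purpose: an ``N``
in a *sequence* is an unknown (or erased) base and matches nothing except
the wildcard code ``N`` in a word, so erased motif occurrences can never
re-match a concrete word.
"""

from __future__ import annotations

import re
from functools import lru_cache

IUPAC_ALPHABET = "ACGTRYSWKMBDHVN"

#: base set denoted by each IUPAC code
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

CODE_FOR_BASES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_BASES.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: for each code, the codes whose base set is a strict superset (used by
#: the single-position generalization step of motif discovery)
STRICT_SUPERSETS: dict[str, tuple[str, ...]] = {
    code: tuple(
        c for c in IUPAC_ALPHABET
        if IUPAC_BASES[code] < IUPAC_BASES[c]
    )
    for code in IUPAC_ALPHABET
}

_RC_TABLE = str.maketrans(COMPLEMENT)


def bases(code: str) -> frozenset[str]:
    """Base set of a single IUPAC code; raises ``ValueError`` on junk."""
    try:
        return IUPAC_BASES[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC code: {code!r}") from None


def validate_word(word: str) -> str:
    if not word:
        raise ValueError("empty IUPAC word")
    for ch in word:
        if ch not in IUPAC_BASES:
            raise ValueError(f"invalid IUPAC letter {ch!r} in word {word!r}")
    return word


def revcomp(s: str) -> str:
    """Reverse complement of a sequence or IUPAC word."""
    try:
        return s.translate(_RC_TABLE)[::-1]
    except Exception:  # pragma: no cover - translate never fails on str
        raise ValueError(f"cannot reverse-complement {s!r}")


def _char_class(code: str) -> str:
    if code not in IUPAC_BASES:
        raise ValueError(f"invalid IUPAC letter {code!r}")
    if code == "N":
        # wildcard: matches unknown sequence bases too
        return "[ACGTN]"
    return "[" + "".join(sorted(IUPAC_BASES[code])) + "]"


@lru_cache(maxsize=65536)
def word_pattern(word: str) -> re.Pattern[str]:
    """Compiled regex matching one occurrence of *word* (forward strand)."""
    return re.compile("".join(_char_class(c) for c in word))


@lru_cache(maxsize=65536)
def _lookahead_pattern(word: str) -> re.Pattern[str]:
    # zero-width so overlapping occurrences are all reported
    return re.compile("(?=" + "".join(_char_class(c) for c in word) + ")")


def contains_word(seq: str, word: str, both_strands: bool = True) -> bool:
    """True iff some window of ``seq`` (or of its reverse complement when
    ``both_strands``) matches ``word`` position-wise under IUPAC semantics.
    """
    validate_word(word)
    if word_pattern(word).search(seq):
        return True
    if both_strands:
        rc = revcomp(word)
        if rc != word and word_pattern(rc).search(seq):
            return True
    return False


def match_positions(seq: str, word: str, both_strands: bool = True) -> set[int]:
    """0-based sequence positions covered by any occurrence of ``word``.

    Reverse-strand occurrences are reported as forward-strand coordinates
    (an occurrence of ``word`` on the minus strand is an occurrence of its
    reverse complement on the plus strand).
    """
    validate_word(word)
    L = len(word)
    words = {word}
    if both_strands:
        words.add(revcomp(word))
    covered: set[int] = set()
    for w in words:
        for m in _lookahead_pattern(w).finditer(seq):
            covered.update(range(m.start(), m.start() + L))
    return covered
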