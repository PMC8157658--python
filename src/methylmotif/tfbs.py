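"""Matching discovered motifs against a transcription-factor PWM database.

Database motifs are position frequency matrices (PFMs) in MEME minimal
motif format (the interchange format of JASPAR exports).  A discovered
consensus is turned into a query PFM (uniform distribution over each
IUPAC code's bases), slid ungapped across each database PFM in both
orientations, and the best configuration is the one maximizing the mean
per-column similarity

    column_score(p, q) = 1 − ‖p − q‖₂ / √2

(√2 is the largest possible Euclidean distance between two probability
vectors on four outcomes, so the score lies in [0, 1] and is defined for
every column, uniform ones included).  Significance is assessed with a
Monte-Carlo null: the same best-configuration score against
column-shuffled copies of the target, with an add-one p-value estimator
so p is never zero.  E-values multiply by the database size and q-values
are Benjamini–Hochberg over the per-database p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .iupac import bases, validate_word

logger = logging.getLogger(__name__)

_BASE_ORDER = "ACGT"
_SQRT2 = math.sqrt(2.0)


@dataclass
class PFM:
    """Position frequency matrix: one probability 4-vector (A,C,G,T) per column."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray  # shape (width, 4)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise DataError(
                f"PFM {self.motif_id}: matrix must be (width >= 1, 4), got {m.shape}"
            )
        if np.any(m < 0):
            raise DataError(f"PFM {self.motif_id}: negative probabilities")
        sums = m.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise DataError(
                f"PFM {self.motif_id}: column {bad[0] + 1} sums to {sums[bad[0]]:.6f}, not 1"
            )
        self.matrix = m

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def revcomp(self) -> "PFM":
        """Reverse complement: reversed columns with A<->T and C<->G swapped."""
        return PFM(self.motif_id, self.tf_name, self.matrix[::-1, ::-1].copy())


@dataclass
class TFMatch:
    """One query-motif / database-PWM match."""

    query_id: str
    target_id: str
    tf_name: str
    score: float
    offset: int
    orientation: str  # '+' or '-'
    overlap: int
    pvalue: float
    evalue: float
    qvalue: float


def read_meme_motifs(path: str | Path) -> list[PFM]:
    """Parse a MEME minimal motif file into PFMs.

    Requires per motif a ``MOTIF <id> [<name>]`` line followed by a
    ``letter-probability matrix: ... w= <w> ...`` line and ``w`` rows of 4
    probabilities.  Malformed rows are hard errors naming the motif and
    the line number; a file with zero MOTIF blocks parses to an empty
    list with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    pfms: list[PFM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line.startswith("MOTIF"):
            i += 1
            continue
        parts = line.split()
        if len(parts) < 2:
            raise DataError(f"{path}:{i + 1}: MOTIF line without an identifier")
        motif_id = parts[1]
        tf_name = parts[2] if len(parts) > 2 else motif_id
        # find the letter-probability header
        j = i + 1
        while j < len(lines) and not lines[j].strip().startswith("letter-probability matrix"):
            if lines[j].strip().startswith("MOTIF"):
                raise DataError(
                    f"{path}:{i + 1}: motif {motif_id} has no letter-probability matrix"
                )
            j += 1
        if j >= len(lines):
            raise DataError(
                f"{path}:{i + 1}: motif {motif_id} has no letter-probability matrix"
            )
        header = lines[j]
        width = None
        toks = header.replace("=", " = ").split()
        for k, tok in enumerate(toks):
            if tok == "w" and k + 2 < len(toks) and toks[k + 1] == "=":
                width = int(toks[k + 2])
        if width is None:
            raise DataError(f"{path}:{j + 1}: motif {motif_id}: missing w= in matrix header")
        rows = []
        for r in range(width):
            lineno = j + 1 + r
            if lineno >= len(lines):
                raise DataError(
                    f"{path}:{lineno + 1}: motif {motif_id}: matrix truncated "
                    f"({r} of {width} rows)"
                )
            fields = lines[lineno].split()
            try:
                vals = [float(x) for x in fields]
            except ValueError:
                raise DataError(
                    f"{path}:{lineno + 1}: motif {motif_id}: malformed matrix row "
                    f"{lines[lineno]!r}"
                ) from None
            if len(vals) != 4:
                raise DataError(
                    f"{path}:{lineno + 1}: motif {motif_id}: expected 4 probabilities, "
                    f"got {len(vals)}"
                )
            rows.append(vals)
        try:
            pfms.append(PFM(motif_id, tf_name, np.array(rows)))
        except DataError as exc:
            raise DataError(f"{path}:{j + 2}: {exc}") from None
        i = j + 1 + width
    if not pfms:
        logger.warning("%s: no MOTIF blocks found", path)
    return pfms


def write_meme_motifs(pfms: Sequence[PFM], path: str | Path) -> None:
    """Write PFMs in MEME minimal motif format (deterministic bytes)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for pfm in pfms:
            fh.write(f"MOTIF {pfm.motif_id} {pfm.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pfm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pfm.matrix:
                fh.write(" ".join(f"{x:.8f}" for x in row) + "\n")
            fh.write("\n")


def consensus_to_pfm(consensus: str, motif_id: str | None = None, tf_name: str = "") -> PFM:
    """Uniform-over-code-bases PFM for an IUPAC consensus (W -> A:0.5, T:0.5)."""
    validate_word(consensus)
    cols = np.zeros((len(consensus), 4))
    for i, code in enumerate(consensus):
        bs = bases(code)
        for b in bs:
            cols[i, _BASE_ORDER.index(b)] = 1.0 / len(bs)
    return PFM(motif_id or consensus, tf_name or (motif_id or consensus), cols)


def occurrence_pfm(
    consensus: str,
    flank_seqs: Sequence[str],
    motif_id: str | None = None,
    pseudocount: float = 0.25,
) -> PFM:
    """PFM estimated from the motif's actual occurrences in the flanks.

    Forward-strand occurrences of the consensus are stacked and base
    frequencies per column are computed with an add-``pseudocount``
    smoothing; falls back to the uniform consensus PFM when the motif
    never occurs.
    """
    from .iupac import word_pattern, revcomp

    validate_word(consensus)
    L = len(consensus)
    counts = np.full((L, 4), pseudocount)
    pats = {word_pattern(consensus)}
    rc = revcomp(consensus)
    n_hits = 0
    for seq in flank_seqs:
        for pat, flip in ((word_pattern(consensus), False), ((word_pattern(rc), True) if rc != consensus else (None, False)),):
            if pat is None:
                continue
            for m in pat.finditer(seq):
                frag = seq[m.start():m.start() + L]
                if flip:
                    frag = revcomp(frag)
                for i, b in enumerate(frag):
                    if b in _BASE_ORDER:
                        counts[i, _BASE_ORDER.index(b)] += 1
                n_hits += 1
    if n_hits == 0:
        return consensus_to_pfm(consensus, motif_id)
    probs = counts / counts.sum(axis=1, keepdims=True)
    return PFM(motif_id or consensus, motif_id or consensus, probs)


def column_score(p: Sequence[float], q: Sequence[float]) -> float:
    """Similarity of two probability columns: 1 − Euclidean distance / √2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(max(0.0, 1.0 - np.linalg.norm(p - q) / _SQRT2))


def _best_configuration(qm: np.ndarray, tm: np.ndarray, min_overlap: int):
    """Best (score, offset, overlap) over ungapped offsets of qm vs tm."""
    wq, wt = qm.shape[0], tm.shape[0]
    best = None
    for offset in range(min_overlap - wq, wt - min_overlap + 1):
        q_lo = max(0, -offset)
        t_lo = max(0, offset)
        overlap = min(wq - q_lo, wt - t_lo)
        if overlap < min_overlap:
            continue
        qseg = qm[q_lo:q_lo + overlap]
        tseg = tm[t_lo:t_lo + overlap]
        colscores = 1.0 - np.linalg.norm(qseg - tseg, axis=1) / _SQRT2
        score = float(np.clip(colscores, 0.0, None).mean())
        key = (score, -abs(offset))
        if best is None or key > best[0]:
            best = (key, offset, overlap, score)
    if best is None:
        return None
    return best[3], best[1], best[2]


def compare_motifs(query: PFM, target: PFM, min_overlap: int = 1):
    """Best ungapped alignment of query against target over both orientations.

    Returns ``(score, offset, orientation, overlap)`` maximizing the mean
    column score over the overlap; ties prefer the smaller absolute
    offset, then the '+' orientation.  Returns ``None`` when no offset
    satisfies ``min_overlap`` ("no valid alignment").
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    best = None
    for orientation, qm in (("+", query.matrix), ("-", query.revcomp().matrix)):
        cfg = _best_configuration(qm, target.matrix, min_overlap)
        if cfg is None:
            continue
        score, offset, overlap = cfg
        key = (score, -abs(offset), 1 if orientation == "+" else 0)
        if best is None or key > best[0]:
            best = (key, score, offset, orientation, overlap)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


def bh_qvalues(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


@dataclass
class TFBSThresholds:
    """Conjunctive filters on the reported matches (defaults mirror typical use)."""

    p: float = 0.05
    e: float = 10.0
    q: float = 1.0
    overlap: int = 1


def match_tfbs(
    query: PFM,
    db: Sequence[PFM],
    thresholds: TFBSThresholds | None = None,
    n_null: int = 1000,
    seed: int = 0,
) -> list[TFMatch]:
    """Query one motif against a PFM database with Monte-Carlo significance.

    For each database PFM the observed best-configuration score is
    compared with ``n_null`` scores against column-shuffled copies of
    that PFM (seeded, per-target RNG streams so results do not depend on
    database order); p = (1 + #{null > observed}) / (1 + n_null),
    E = p × database size, q = BH over the per-database p-values.

    Null scores are counted when they *strictly* exceed the observed
    score: the column shuffle preserves the target's column multiset, so
    whenever the query matches the target perfectly a short overlap
    against one identical column re-attains the observed score exactly,
    and counting such ties would make perfect matches maximally
    insignificant.  For continuous (non-degenerate) columns exact ties
    have probability zero and the two counting rules agree.
    Matches passing all four thresholds are returned sorted by ascending
    p (ties by target id).
    """
    if not db:
        raise ValueError("PFM database is empty")
    if n_null < 1:
        raise ValueError(f"n_null must be >= 1, got {n_null}")
    thresholds = thresholds or TFBSThresholds()
    results = []
    pvals: list[float] = []
    for idx, target in enumerate(db):
        obs = compare_motifs(query, target, thresholds.overlap)
        if obs is None:
            pvals.append(1.0)
            results.append(None)
            continue
        score, offset, orientation, overlap = obs
        rng = np.random.default_rng([seed % (2**31), idx])
        exceed = 0
        tm = target.matrix
        for _ in range(n_null):
            perm = rng.permutation(tm.shape[0])
            shuffled = PFM(target.motif_id, target.tf_name, tm[perm])
            null_cfg = compare_motifs(query, shuffled, thresholds.overlap)
            if null_cfg is not None and null_cfg[0] > score:
                exceed += 1
        p = (1 + exceed) / (1 + n_null)
        pvals.append(p)
        results.append((target, score, offset, orientation, overlap, p))
    qvals = bh_qvalues(pvals)
    matches: list[TFMatch] = []
    for res, p, q in zip(results, pvals, qvals):
        if res is None:
            continue
        target, score, offset, orientation, overlap, _ = res
        e = p * len(db)
        if p <= thresholds.p and e <= thresholds.e and q <= thresholds.q:
            matches.append(
                TFMatch(
                    query_id=query.motif_id,
                    target_id=target.motif_id,
                    tf_name=target.tf_name,
                    score=score,
                    offset=offset,
                    orientation=orientation,
                    overlap=overlap,
                    pvalue=p,
                    evalue=e,
                    qvalue=q,
                )
            )
    matches.sort(key=lambda m: (m.pvalue, m.target_id))
    return matches
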