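"""Methylation-unbalance annotation of discovered motifs.

Each motif's *supporting set* is the set of target CpGs whose flanking
sequence contains the motif consensus (strand-aware).  The unbalance of
hyper- vs hypo-methylated CpGs inside that set, relative to the whole
target set (the universe), is tested with a two-sided Fisher exact test
on the contingency table

    [[hyper_in_support, hypo_in_support],
     [hyper_in_universe, hypo_in_universe]]

and the motif is classed ``hyper``/``hypo``/``neutral`` by a majority
threshold combined with the test: the majority fraction must reach the
unbalance threshold AND the unbalance p-value must pass its own
threshold, otherwise the motif is neutral.  The default unbalance
p-value threshold of 1.0 makes the p-filter inert, so classification is
purely by majority fraction unless the user tightens it.

The universe defaults to the full target set (hyper + hypo), which is
always status-labelled; a user-supplied labelled universe can be passed
instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .cpg_io import CpGRecord, FlankSequence
from .discovery import Motif, fisher_exact_2x2
from .errors import DataError
from .iupac import contains_word

TRENDS = ("hyper", "hypo", "neutral")


@dataclass
class MethylAnnotation:
    """Methylation-unbalance summary of one motif's supporting set."""

    motif_consensus: str
    n_hyper: int
    n_hypo: int
    meth_ratio: float          # n_hyper / n_hypo, +inf when n_hypo == 0
    unbalance_p: float
    trend: str

    def ratio_str(self) -> str:
        """Serialized ratio; infinite ratios render as the literal ``Inf``."""
        return "Inf" if math.isinf(self.meth_ratio) else repr(self.meth_ratio)


def supporting_set(motif: Motif | str, target_flanks: Iterable[FlankSequence]) -> list[str]:
    """IDs of target CpGs whose flank contains the motif (either strand).

    Deduplicated, preserving input order.
    """
    consensus = motif.consensus if isinstance(motif, Motif) else motif
    seen: set[str] = set()
    out: list[str] = []
    for flank in target_flanks:
        if flank.cpg_id in seen:
            continue
        if contains_word(flank.seq, consensus, both_strands=True):
            seen.add(flank.cpg_id)
            out.append(flank.cpg_id)
    return out


def methylation_stats(
    supporting: Sequence[CpGRecord],
    universe: Sequence[CpGRecord],
    unbalance_threshold: float = 0.7,
    p_threshold: float = 1.0,
    motif_consensus: str = "",
) -> MethylAnnotation:
    """Hyper/hypo counts, ratio, unbalance test and trend class for one motif."""
    if not (0.5 < unbalance_threshold <= 1):
        raise ValueError(
            f"unbalance_threshold must be in (0.5, 1], got {unbalance_threshold}"
        )
    if not supporting:
        raise DataError(
            f"motif {motif_consensus or '<unnamed>'}: empty supporting set"
        )
    for rec in supporting:
        if rec.status not in ("hyper", "hypo"):
            raise DataError(
                f"motif {motif_consensus}: supporting CpG {rec.cpg_id} has "
                f"status {rec.status!r}; expected hyper or hypo"
            )
    n_hyper = sum(1 for r in supporting if r.status == "hyper")
    n_hypo = len(supporting) - n_hyper
    u_hyper = sum(1 for r in universe if r.status == "hyper")
    u_hypo = sum(1 for r in universe if r.status == "hypo")
    p = fisher_exact_2x2(n_hyper, n_hypo, u_hyper, u_hypo, alternative="two_sided")
    ratio = math.inf if n_hypo == 0 else n_hyper / n_hypo
    frac_hyper = n_hyper / len(supporting)
    trend = "neutral"
    if p <= p_threshold:
        if frac_hyper >= unbalance_threshold:
            trend = "hyper"
        elif (1 - frac_hyper) >= unbalance_threshold:
            trend = "hypo"
    return MethylAnnotation(
        motif_consensus=motif_consensus,
        n_hyper=n_hyper,
        n_hypo=n_hypo,
        meth_ratio=ratio,
        unbalance_p=p,
        trend=trend,
    )


def annotate_motif(
    motif: Motif,
    target_flanks: Sequence[FlankSequence],
    target_records: Sequence[CpGRecord],
    unbalance_threshold: float = 0.7,
    p_threshold: float = 1.0,
) -> tuple[list[str], MethylAnnotation]:
    """Supporting set plus methylation annotation for one motif.

    The supporting set is recomputed on the (un-erased) flanks; the
    universe is the full target record set.
    """
    support_ids = supporting_set(motif, target_flanks)
    by_id = {r.cpg_id: r for r in target_records}
    support_records = [by_id[i] for i in support_ids if i in by_id]
    ann = methylation_stats(
        support_records,
        target_records,
        unbalance_threshold=unbalance_threshold,
        p_threshold=p_threshold,
        motif_consensus=motif.consensus,
    )
    return support_ids, ann
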