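"""Input parsing and CpG flanking-sequence extraction.

Coordinate conventions
----------------------
Annotation positions are 1-based and point at the **C** of the CpG
dinucleotide (the convention of Illumina manifest MAPINFO columns).
All internal genomic intervals are 0-based half-open; every writer that
emits intervals states this in its header comment.

For a CpG with 1-based cytosine position ``p`` and flank size ``w`` the
extracted window is the 1-based inclusive interval ``[p - w, p + 1 + w]``
(``w`` bases upstream of the C through ``w`` bases downstream of the G),
so a non-truncated flank has length ``2 w + 2``.  Flanks are always
reported on the forward strand of the reference; downstream motif search
is strand-aware, so the annotation strand is stored but not used here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError

logger = logging.getLogger(__name__)

VALID_STATUS = ("hyper", "hypo", "none")

_SEQ_CLEAN = str.maketrans(
    "acgtn", "ACGTN"
)


@dataclass(frozen=True)
class CpGRecord:
    """One CpG probe: identifier, methylation call and optional effect size.

    ``status`` is ``hyper``/``hypo`` for target probes and ``none`` for
    background probes (the background universe carries no methylation
    call).  When a signed methylation difference ``delta`` is present its
    sign must agree with the status.
    """

    cpg_id: str
    status: str = "none"
    delta: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.cpg_id or any(c.isspace() for c in self.cpg_id):
            raise DataError(f"invalid cpg_id {self.cpg_id!r}")
        if self.status not in VALID_STATUS:
            raise DataError(
                f"unknown methylation status {self.status!r} for {self.cpg_id}"
            )
        if self.delta is not None:
            if self.status == "hyper" and not self.delta > 0:
                raise DataError(
                    f"{self.cpg_id}: status=hyper requires delta > 0, got {self.delta}"
                )
            if self.status == "hypo" and not self.delta < 0:
                raise DataError(
                    f"{self.cpg_id}: status=hypo requires delta < 0, got {self.delta}"
                )


@dataclass
class CpGAnnotation:
    """Mapping cpg_id -> (chrom, 1-based position of the CpG cytosine, strand)."""

    entries: dict[str, tuple[str, int, str]] = field(default_factory=dict)

    def add(self, cpg_id: str, chrom: str, pos: int, strand: str = "unknown") -> None:
        if cpg_id in self.entries:
            raise DataError(f"duplicate cpg_id in annotation: {cpg_id!r}")
        if pos < 1:
            raise DataError(f"{cpg_id}: position must be >= 1, got {pos}")
        if strand not in ("+", "-", "unknown"):
            raise DataError(f"{cpg_id}: invalid strand {strand!r}")
        self.entries[cpg_id] = (chrom, pos, strand)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, cpg_id: str) -> bool:
        return cpg_id in self.entries

    def __getitem__(self, cpg_id: str) -> tuple[str, int, str]:
        return self.entries[cpg_id]


@dataclass
class FlankSequence:
    """Forward-strand DNA window around a CpG.

    ``start``/``end`` are 0-based half-open genomic coordinates; for a
    non-truncated flank ``end - start == 2 w + 2`` and ``seq[w:w+2] == "CG"``
    whenever the annotated position truly points at a forward-strand CpG.
    """

    cpg_id: str
    seq: str
    chrom: str
    start: int
    end: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise DataError(
                f"{self.cpg_id}: interval [{self.start},{self.end}) does not "
                f"match sequence length {len(self.seq)}"
            )


def parse_annotation(path: str | Path) -> CpGAnnotation:
    """Parse a CpG annotation TSV (header: cpg_id, chrom, pos[, strand])."""
    path = Path(path)
    ann = CpGAnnotation()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise DataError(f"{path}: empty annotation file (no header)")
        cols = header.rstrip("\n").split("\t")
        try:
            i_id = cols.index("cpg_id")
            i_chrom = cols.index("chrom")
            i_pos = cols.index("pos")
        except ValueError:
            raise DataError(
                f"{path}: annotation header must contain cpg_id, chrom, pos; got {cols}"
            ) from None
        i_strand = cols.index("strand") if "strand" in cols else None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                pos = int(fields[i_pos])
            except (ValueError, IndexError):
                raise DataError(
                    f"{path}:{lineno}: non-integer position "
                    f"{fields[i_pos] if len(fields) > i_pos else '<missing>'!r}"
                ) from None
            strand = fields[i_strand] if i_strand is not None and len(fields) > i_strand else "unknown"
            ann.add(fields[i_id], fields[i_chrom], pos, strand or "unknown")
    if len(ann) == 0:
        logger.warning("%s: annotation contains a header but no data rows", path)
    return ann


def parse_cpg_table(path: str | Path, kind: str) -> list[CpGRecord]:
    """Parse a target or background CpG table.

    Target tables require columns ``cpg_id``, ``status``, ``delta`` (one
    optional label column is kept); background tables require only
    ``cpg_id`` and any extra columns are ignored.
    """
    if kind not in ("target", "background"):
        raise ValueError(f"kind must be 'target' or 'background', got {kind!r}")
    path = Path(path)
    records: list[CpGRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise DataError(f"{path}: empty table (no header)")
        cols = header.rstrip("\n").split("\t")
        if "cpg_id" not in cols:
            raise DataError(f"{path}: missing mandatory column cpg_id")
        i_id = cols.index("cpg_id")
        if kind == "target":
            for required in ("status", "delta"):
                if required not in cols:
                    raise DataError(f"{path}: missing mandatory column {required}")
            i_status = cols.index("status")
            i_delta = cols.index("delta")
            extra = [i for i, c in enumerate(cols) if i not in (i_id, i_status, i_delta)]
            i_label = extra[0] if extra else None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            cpg_id = fields[i_id]
            try:
                if kind == "background":
                    records.append(CpGRecord(cpg_id, status="none"))
                    continue
                status = fields[i_status]
                if status not in ("hyper", "hypo"):
                    raise DataError(
                        f"{path}:{lineno}: unknown status token {status!r}"
                    )
                raw_delta = fields[i_delta].strip()
                delta = float(raw_delta.replace("−", "-")) if raw_delta not in ("", "NA") else None
                label = (
                    fields[i_label]
                    if i_label is not None and len(fields) > i_label
                    else None
                )
                records.append(CpGRecord(cpg_id, status=status, delta=delta, label=label))
            except DataError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from None
    return records


def _contig_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) from a pyfaidx Fasta or a plain chrom->str mapping."""
    frag = genome[chrom][start:end]
    return str(frag)


def extract_flanks(
    genome,
    cpgs: Iterable[CpGRecord],
    annotation: CpGAnnotation,
    w: int,
) -> list[FlankSequence]:
    """Extract the ``2w + 2`` window around each CpG (order-preserving).

    ``genome`` may be a :class:`pyfaidx.Fasta` or any mapping from
    chromosome name to sequence string.  CpGs missing from the annotation
    are skipped with a warning; a chromosome missing from the genome is a
    hard error.  Windows overrunning a contig boundary are truncated and
    flagged.  Output is uppercase with non-ACGT letters mapped to N.
    """
    if w < 1:
        raise ValueError(f"flank size w must be >= 1, got {w}")
    flanks: list[FlankSequence] = []
    n_skipped = 0
    for rec in cpgs:
        if rec.cpg_id not in annotation:
            n_skipped += 1
            logger.warning("cpg_id %s absent from annotation; skipped", rec.cpg_id)
            continue
        chrom, pos, _strand = annotation[rec.cpg_id]
        try:
            clen = _contig_length(genome, chrom)
        except KeyError:
            raise DataError(f"chromosome {chrom!r} (cpg {rec.cpg_id}) absent from genome") from None
        start = pos - 1 - w          # 0-based start of [p-w, p+1+w]
        end = pos + 1 + w            # 0-based exclusive end
        t_start, t_end = max(start, 0), min(end, clen)
        truncated = (t_start, t_end) != (start, end)
        if truncated:
            logger.warning(
                "flank of %s truncated at contig boundary (%s:[%d,%d) -> [%d,%d))",
                rec.cpg_id, chrom, start, end, t_start, t_end,
            )
        seq = _fetch(genome, chrom, t_start, t_end).translate(_SEQ_CLEAN).upper()
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
        if not truncated and seq[w:w + 2] != "CG":
            logger.warning(
                "flank of %s does not carry CG at the annotated position "
                "(found %r); non-CpG cytosine context?",
                rec.cpg_id, seq[w:w + 2],
            )
        flanks.append(
            FlankSequence(rec.cpg_id, seq, chrom, t_start, t_end, truncated=truncated)
        )
    if n_skipped:
        logger.warning("%d CpG record(s) skipped (absent from annotation)", n_skipped)
    return flanks


def write_flanks_fasta(flanks: Iterable[FlankSequence], path: str | Path) -> None:
    """Write flanks to FASTA; the description carries the 0-based interval."""
    records = [
        SeqRecord(
            Seq(f.seq),
            id=f.cpg_id,
            description=f"{f.chrom}:{f.start}-{f.end}",
        )
        for f in flanks
    ]
    SeqIO.write(records, str(path), "fasta")


def read_flanks_fasta(path: str | Path) -> list[FlankSequence]:
    """Re-read a flank FASTA written by :func:`write_flanks_fasta`."""
    out: list[FlankSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        chrom, start, end = "unknown", 0, len(rec.seq)
        parts = rec.description.split()
        if len(parts) > 1 and ":" in parts[1] and "-" in parts[1]:
            chrom, interval = parts[1].rsplit(":", 1)
            s, e = interval.split("-")
            start, end = int(s), int(e)
        out.append(FlankSequence(rec.id, str(rec.seq).upper(), chrom, start, end))
    return out
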