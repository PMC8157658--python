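"""Seeded synthetic genomes, CpG sets and PWM databases with planted signal.

The generator builds a toy multi-chromosome genome with i.i.d. bases at a
chosen GC content, places CpG dinucleotides on a regular grid (so flanks
never overlap each other or a contig boundary and every annotated
position is guaranteed to carry ``CG``), then plants one realization of
an IUPAC word into the flank of a controlled fraction of target and
background CpGs, never overwriting the central CG.  Methylation statuses
are drawn per-CpG with separate hyper probabilities for planted and
unplanted targets, and a ground-truth manifest records exactly which
CpGs were planted, where, and with which realization.

Everything is driven by a single integer seed through independent
``numpy`` generator streams per stage, so every artifact (FASTA, TSVs,
MEME file, manifest) is byte-identical across runs with the same
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cpg_io import CpGAnnotation, CpGRecord
from .iupac import bases, validate_word
from .tfbs import PFM, consensus_to_pfm, write_meme_motifs

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic fixture.

    Defaults emulate a small methylation-array experiment: 300 target and
    300 background CpGs with 20-bp flanks (42-bp windows), a 7-letter
    planted word present in 40% of target vs 2% of background flanks,
    hyper-methylation at 90% among planted targets vs 50% otherwise, and
    human-like 41% GC background sequence.  ``set_words`` carries one
    planted word per target set; the default is a single set.
    """

    seed: int = 1
    n_chrom: int = 2
    chrom_len: int = 20000
    n_target: int = 300
    n_background: int = 300
    flank_w: int = 20
    planted_word: str = "TGAWAAA"
    f_plant_target: float = 0.40
    f_plant_background: float = 0.02
    hyper_fraction_with_motif: float = 0.90
    hyper_fraction_without: float = 0.50
    gc_content: float = 0.41
    n_db_motifs: int = 10
    set_words: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("f_plant_target", "f_plant_background",
                     "hyper_fraction_with_motif", "hyper_fraction_without"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0 < self.gc_content < 1):
            raise ValueError(f"gc_content must be in (0, 1), got {self.gc_content}")
        if self.chrom_len <= 2 * self.flank_w + 2:
            raise ValueError(
                f"chrom_len {self.chrom_len} too small for flank_w {self.flank_w}"
            )
        for word in self.words:
            validate_word(word)
            if len(word) > self.flank_w:
                raise ValueError(
                    f"planted word {word!r} does not fit beside the central CG "
                    f"of a {2 * self.flank_w + 2}-bp flank"
                )

    @property
    def words(self) -> tuple[str, ...]:
        return self.set_words if self.set_words else (self.planted_word,)

    @property
    def n_cpgs(self) -> int:
        return len(self.words) * self.n_target + self.n_background


@dataclass
class SimulatedStudy:
    """In-memory bundle of every artifact of one simulation."""

    config: SimulationConfig
    genome: dict[str, str]
    annotation: CpGAnnotation
    target_sets: dict[str, list[CpGRecord]]
    background: list[CpGRecord]
    manifest: pd.DataFrame
    pfm_db: list[PFM] = field(default_factory=list)


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], CpGAnnotation]:
    """Random genome plus a CpG annotation whose flanks are boundary-safe.

    CpG slots sit on a regular grid with stride > 2w+2 so flanks are
    pairwise disjoint; the sequence is edited to guarantee ``CG`` at
    every annotated (1-based, C) position.
    """
    w = config.flank_w
    stride = 2 * w + 4
    margin = w + 1
    slots: list[tuple[str, int]] = []
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        # 1-based positions p with p >= w+1 and p + 1 + w <= chrom_len
        p = margin
        while p + 1 + w <= config.chrom_len:
            slots.append((chrom, p))
            p += stride
    if config.n_cpgs > len(slots):
        raise ValueError(
            f"too many CpGs for the genome size: {config.n_cpgs} requested, "
            f"{len(slots)} slots available"
        )
    rng = np.random.default_rng([config.seed % (2**31), 0])
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome: dict[str, bytearray] = {}
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        seq = rng.choice(_BASES, size=config.chrom_len, p=probs)
        genome[chrom] = bytearray("".join(seq), "ascii")
    chosen_idx = np.sort(rng.choice(len(slots), size=config.n_cpgs, replace=False))
    annotation = CpGAnnotation()
    for i, slot_i in enumerate(chosen_idx):
        chrom, pos = slots[slot_i]
        genome[chrom][pos - 1] = ord("C")
        genome[chrom][pos] = ord("G")
        annotation.add(f"cg{i + 1:06d}", chrom, pos, "+")
    return {c: s.decode("ascii") for c, s in genome.items()}, annotation


def _realize(word: str, rng: np.random.Generator) -> str:
    return "".join(
        c if c in "ACGT" else rng.choice(sorted(bases(c))) for c in word
    )


def plant_motif(
    genome: dict[str, str],
    annotation: CpGAnnotation,
    config: SimulationConfig,
) -> SimulatedStudy:
    """Plant the configured word(s) into target/background flanks.

    Exactly ``round(f * n)`` flanks per set are planted (deterministic
    count, seeded choice of which); the planted realization is written at
    a seeded offset that avoids the central CG dinucleotide.  Statuses
    are drawn per CpG; the manifest records the full ground truth.
    """
    rng = np.random.default_rng([config.seed % (2**31), 1])
    w = config.flank_w
    ids = list(annotation.entries)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    words = config.words
    set_ids = {
        f"set{k + 1}": perm[k * config.n_target:(k + 1) * config.n_target]
        for k in range(len(words))
    }
    bg_start = len(words) * config.n_target
    background_ids = perm[bg_start:bg_start + config.n_background]

    mutable = {c: bytearray(s, "ascii") for c, s in genome.items()}
    rows = []
    target_sets: dict[str, list[CpGRecord]] = {}

    def plant_into(cpg_id: str, word: str) -> tuple[int, str]:
        chrom, pos, _ = annotation[cpg_id]
        flank_start = pos - 1 - w  # 0-based
        L = len(word)
        # window offsets avoiding the central CG at window positions [w, w+2)
        valid = [o for o in range(2 * w + 2 - L + 1) if o + L <= w or o >= w + 2]
        offset = int(rng.choice(valid))
        realization = _realize(word, rng)
        mutable[chrom][flank_start + offset:flank_start + offset + L] = (
            realization.encode("ascii")
        )
        return offset, realization

    for label, word in zip(set_ids, words):
        sids = set_ids[label]
        n_plant = round(config.f_plant_target * len(sids))
        planted = set(sids[i] for i in rng.permutation(len(sids))[:n_plant])
        records = []
        for cpg_id in sids:
            offset, realization = plant_into(cpg_id, word) if cpg_id in planted else (None, None)
            p_hyper = (
                config.hyper_fraction_with_motif
                if cpg_id in planted
                else config.hyper_fraction_without
            )
            status = "hyper" if rng.random() < p_hyper else "hypo"
            delta = round(float(rng.uniform(0.05, 0.5)), 4)
            if status == "hypo":
                delta = -delta
            records.append(CpGRecord(cpg_id, status=status, delta=delta, label=label))
            chrom, pos, _ = annotation[cpg_id]
            rows.append(
                dict(cpg_id=cpg_id, set_label=label, chrom=chrom, pos=pos,
                     planted=cpg_id in planted, offset=offset,
                     realization=realization, status=status)
            )
        target_sets[label] = records

    n_plant_bg = round(config.f_plant_background * len(background_ids))
    planted_bg = set(
        background_ids[i] for i in rng.permutation(len(background_ids))[:n_plant_bg]
    )
    background = []
    bg_word = words[0]
    for cpg_id in background_ids:
        offset, realization = (
            plant_into(cpg_id, bg_word) if cpg_id in planted_bg else (None, None)
        )
        background.append(CpGRecord(cpg_id, status="none"))
        chrom, pos, _ = annotation[cpg_id]
        rows.append(
            dict(cpg_id=cpg_id, set_label="background", chrom=chrom, pos=pos,
                 planted=cpg_id in planted_bg, offset=offset,
                 realization=realization, status="none")
        )

    manifest = pd.DataFrame(rows)
    new_genome = {c: s.decode("ascii") for c, s in mutable.items()}
    return SimulatedStudy(
        config=config,
        genome=new_genome,
        annotation=annotation,
        target_sets=target_sets,
        background=background,
        manifest=manifest,
    )


def generate_pfm_db(
    n: int,
    seed: int = 0,
    include_query: PFM | None = None,
) -> list[PFM]:
    """Random Dirichlet-column PFMs (widths 5..12), optionally embedding a query."""
    if n < 1 and include_query is None:
        raise ValueError("requested an empty PFM database")
    rng = np.random.default_rng([seed % (2**31), 2])
    pfms: list[PFM] = []
    for i in range(n):
        width = int(rng.integers(5, 13))
        cols = rng.dirichlet([0.7, 0.7, 0.7, 0.7], size=width)
        pfms.append(PFM(f"DB{i + 1:03d}", f"TF{i + 1}", cols))
    if include_query is not None:
        pfms.append(include_query)
    return pfms


def simulate_study(config: SimulationConfig, with_db: bool = True) -> SimulatedStudy:
    """Full fixture: genome + annotation + planted CpG sets (+ PFM database).

    The database embeds a PFM built from the first planted word so
    downstream TFBS matching has a guaranteed positive control.
    """
    genome, annotation = generate_genome(config)
    study = plant_motif(genome, annotation, config)
    if with_db:
        query = consensus_to_pfm(
            config.words[0], motif_id=f"PLANTED_{config.words[0]}", tf_name="PLANTED"
        )
        study.pfm_db = generate_pfm_db(config.n_db_motifs, config.seed, include_query=query)
    return study


def write_fasta(genome: dict[str, str], path: str | Path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact to ``outdir``; returns the path of each file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta(study.genome, paths["genome"])

    paths["annotation"] = outdir / "annotation.tsv"
    with open(paths["annotation"], "w") as fh:
        fh.write("cpg_id\tchrom\tpos\tstrand\n")
        for cpg_id, (chrom, pos, strand) in study.annotation.entries.items():
            fh.write(f"{cpg_id}\t{chrom}\t{pos}\t{strand}\n")

    for label, records in study.target_sets.items():
        p = outdir / f"target_{label}.tsv"
        paths[f"target_{label}"] = p
        with open(p, "w") as fh:
            fh.write("cpg_id\tstatus\tdelta\tlabel\n")
            for r in records:
                fh.write(f"{r.cpg_id}\t{r.status}\t{r.delta}\t{r.label}\n")

    paths["background"] = outdir / "background.tsv"
    with open(paths["background"], "w") as fh:
        fh.write("cpg_id\n")
        for r in study.background:
            fh.write(r.cpg_id + "\n")

    paths["manifest"] = outdir / "truth_manifest.tsv"
    study.manifest.to_csv(paths["manifest"], sep="\t", index=False)

    if study.pfm_db:
        paths["pfm_db"] = outdir / "pfm_db.meme"
        write_meme_motifs(study.pfm_db, paths["pfm_db"])
    return paths
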