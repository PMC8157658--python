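"""End-to-end orchestration: load -> motif analysis -> TFBS analysis.

The pipeline processes each target CpG set independently through flank
extraction, discriminative motif discovery against the shared background
and methylation-unbalance annotation; motifs from all sets are then
clustered jointly (a cross-condition similarity dendrogram) and each is
matched against the PWM database.  Every output is a plain-text table
(CSV/TSV/Newick/JSON) and every source of randomness flows from the
single configured seed, so two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pyfaidx

from . import __version__
from .annotate import MethylAnnotation, annotate_motif
from .cluster import motif_distance_matrix, upgma_cluster
from .cpg_io import (
    extract_flanks,
    parse_annotation,
    parse_cpg_table,
    write_flanks_fasta,
)
from .discovery import DiscoveryParams, Motif, discover_motifs
from .errors import DataError
from .tfbs import TFBSThresholds, consensus_to_pfm, match_tfbs, read_meme_motifs

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = (
    "set_label", "consensus", "length", "pvalue", "evalue",
    "n_pos_with", "n_pos_without", "n_hyper", "n_hypo",
    "meth_ratio", "unbalance_p", "trend", "supporting_cpgs",
)

TFBS_COLUMNS = (
    "query_set", "query_id", "tf_name", "target_id", "score", "offset",
    "orientation", "overlap", "pvalue", "evalue", "qvalue",
)


@dataclass
class PipelineConfig:
    """Paths plus every stage's thresholds (defaults: 20-bp flanks, motif
    p/E 0.05/0.05, unbalance threshold 0.7 with an inert p-filter of 1.0,
    TFBS p 0.05 / E 10 / q 1 / overlap 1)."""

    genome: str
    annotation: str
    targets: list[str]
    background: str
    pfm_db: str
    outdir: str
    flank_w: int = 20
    p_threshold: float = 0.05
    e_threshold: float = 0.05
    k_min: int = 3
    k_max: int = 8
    max_motifs: int = 10
    beam_width: int = 8
    unbalance_threshold: float = 0.7
    unbalance_p_threshold: float = 1.0
    tf_p: float = 0.05
    tf_e: float = 10.0
    tf_q: float = 1.0
    tf_overlap: int = 1
    n_null: int = 1000
    seed: int = 1
    linkage: str = "average"

    def validate_paths(self) -> None:
        for key in ("genome", "annotation", "background", "pfm_db"):
            if not Path(getattr(self, key)).exists():
                raise DataError(f"{key} path does not exist: {getattr(self, key)}")
        for t in self.targets:
            if not Path(t).exists():
                raise DataError(f"targets path does not exist: {t}")


@dataclass
class AnnotatedMotif:
    set_label: str
    motif: Motif
    annotation: MethylAnnotation
    supporting_cpgs: list[str] = field(default_factory=list)


def export_summary(rows: Sequence[AnnotatedMotif], path: str | Path) -> None:
    """RFC-4180 summary CSV, deterministically ordered by (set, p, consensus).

    Infinite methylation ratios serialize as the literal ``Inf``.
    """
    ordered = sorted(
        rows, key=lambda r: (r.set_label, r.motif.pvalue, r.motif.consensus)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_COLUMNS)
        for r in ordered:
            writer.writerow([
                r.set_label,
                r.motif.consensus,
                r.motif.length,
                repr(r.motif.pvalue),
                repr(r.motif.evalue),
                r.motif.n_pos_with,
                r.motif.n_pos_without,
                r.annotation.n_hyper,
                r.annotation.n_hypo,
                r.annotation.ratio_str(),
                repr(r.annotation.unbalance_p),
                r.annotation.trend,
                ";".join(r.supporting_cpgs),
            ])


def _write_tfbs_csv(rows, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TFBS_COLUMNS)
        for set_label, m in rows:
            writer.writerow([
                set_label, m.query_id, m.tf_name, m.target_id,
                repr(m.score), m.offset, m.orientation, m.overlap,
                repr(m.pvalue), repr(m.evalue), repr(m.qvalue),
            ])


def _write_presence_matrix(rows, motif_labels, path: str | Path) -> None:
    """Binary motif-by-TF matrix behind the TFBS heatmap."""
    tfs = sorted({m.tf_name for _, m in rows})
    hits = {(f"{s}.{m.query_id}", m.tf_name) for s, m in rows}
    with open(path, "w") as fh:
        fh.write("\t".join(["motif", *tfs]) + "\n")
        for lab in motif_labels:
            fh.write("\t".join([lab, *("1" if (lab, tf) in hits else "0" for tf in tfs)]) + "\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full three-step analysis; returns the path of every output."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("load")
        genome = pyfaidx.Fasta(config.genome)
        annotation = parse_annotation(config.annotation)
        background = parse_cpg_table(config.background, "background")
        bg_flanks = extract_flanks(genome, background, annotation, config.flank_w)
        db = read_meme_motifs(config.pfm_db)
        logger.info(
            "loaded %d annotation rows, %d background CpGs, %d database PFMs",
            len(annotation), len(background), len(db),
        )
    except DataError as exc:
        raise DataError(f"stage load: {exc}") from exc

    disc = DiscoveryParams(
        k_min=config.k_min, k_max=config.k_max,
        p_threshold=config.p_threshold, e_threshold=config.e_threshold,
        max_motifs=config.max_motifs, beam_width=config.beam_width,
        seed=config.seed,
    )
    annotated: list[AnnotatedMotif] = []
    for target_path in config.targets:
        label = Path(target_path).stem.removeprefix("target_")
        try:
            stage(f"motif analysis [{label}]")
            records = parse_cpg_table(target_path, "target")
            flanks = extract_flanks(genome, records, annotation, config.flank_w)
            write_flanks_fasta(flanks, outdir / f"flanks_{label}.fa")
            motifs = discover_motifs(
                [f.seq for f in flanks],
                [f.seq for f in bg_flanks],
                disc,
                pos_ids=[f.cpg_id for f in flanks],
            )
            logger.info("set %s: %d target CpGs -> %d motifs", label, len(records), len(motifs))
            for motif in motifs:
                support, meth = annotate_motif(
                    motif, flanks, records,
                    unbalance_threshold=config.unbalance_threshold,
                    p_threshold=config.unbalance_p_threshold,
                )
                annotated.append(AnnotatedMotif(label, motif, meth, support))
        except DataError as exc:
            raise DataError(f"stage motif-analysis[{label}]: {exc}") from exc

    paths["summary"] = outdir / "summary.csv"
    export_summary(annotated, paths["summary"])

    annotated_sorted = sorted(
        annotated, key=lambda r: (r.set_label, r.motif.pvalue, r.motif.consensus)
    )
    motif_labels = [f"{r.set_label}.{r.motif.consensus}" for r in annotated_sorted]

    stage("clustering")
    paths["distance"] = outdir / "distance_matrix.tsv"
    paths["tree"] = outdir / "motifs.nwk"
    if len(annotated_sorted) >= 2:
        dm = motif_distance_matrix(
            [r.motif.consensus for r in annotated_sorted], labels=motif_labels
        )
        dm.to_tsv(paths["distance"])
        trends = {lab: r.annotation.trend for lab, r in zip(motif_labels, annotated_sorted)}
        newick = upgma_cluster(dm, leaf_annotations=trends, linkage=config.linkage)
        paths["tree"].write_text(newick + "\n")
    else:
        logger.warning("fewer than 2 motifs; clustering skipped, empty outputs written")
        paths["distance"].write_text("motif\n")
        paths["tree"].write_text(";\n" if annotated_sorted else "\n")

    stage("tfbs analysis")
    tf_rows = []
    thresholds = TFBSThresholds(
        p=config.tf_p, e=config.tf_e, q=config.tf_q, overlap=config.tf_overlap
    )
    if not db:
        logger.warning("empty PFM database; TFBS analysis skipped")
    for r in annotated_sorted:
        query = consensus_to_pfm(r.motif.consensus)
        if db:
            for m in match_tfbs(query, db, thresholds, n_null=config.n_null, seed=config.seed):
                tf_rows.append((r.set_label, m))
    paths["tfbs"] = outdir / "tfbs.csv"
    _write_tfbs_csv(tf_rows, paths["tfbs"])
    paths["tf_presence"] = outdir / "tf_presence_matrix.tsv"
    _write_presence_matrix(tf_rows, motif_labels, paths["tf_presence"])

    stage("manifest")
    manifest = {
        "package": "methylmotif",
        "version": __version__,
        "parameters": {k: v for k, v in asdict(config).items()},
        "counts": {
            "target_sets": len(config.targets),
            "background_cpgs": len(background),
            "motifs": len(annotated_sorted),
            "tfbs_matches": len(tf_rows),
            "db_pfms": len(db),
        },
        "outputs": {k: str(v) for k, v in sorted(paths.items())},
    }
    paths["manifest"] = outdir / "run_manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
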