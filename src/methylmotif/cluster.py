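"""Consensus-sequence similarity, distances and hierarchical clustering.

Motifs are compared through their IUPAC consensus strings with a global
(end-to-end) pairwise alignment under a probabilistic nucleotide
substitution matrix: the score of aligning codes ``x`` and ``y`` is

    |bases(x) ∩ bases(y)| / (|bases(x)| · |bases(y)|)

i.e. the probability that a base drawn uniformly from ``x`` equals a
base drawn uniformly from ``y`` (so identity scores 1 for concrete
bases, ``W:W`` scores 0.5, ``N:N`` scores 0.25, disjoint codes 0).
Gaps cost ``gap_open + k * gap_extend`` for a run of length ``k``.

Pairwise similarity scores are min-max normalized over the off-diagonal
pairs and the distance is the complement to 1; the diagonal is forced to
zero (self-scores scale with motif length and would otherwise break the
zero-diagonal contract).  Agglomerative clustering (UPGMA by default)
turns the distance matrix into an ultrametric dendrogram exported as a
Newick string, with each leaf label optionally suffixed by the motif's
methylation trend (``CONSENSUS|hyper``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .iupac import IUPAC_ALPHABET, bases, validate_word

logger = logging.getLogger(__name__)


def iupac_substitution_score(x: str, y: str) -> float:
    """Probabilistic match score of two IUPAC codes, in [0, 1]."""
    bx, by = bases(x), bases(y)
    return len(bx & by) / (len(bx) * len(by))


def _build_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet=IUPAC_ALPHABET, dims=2)
    for x in IUPAC_ALPHABET:
        for y in IUPAC_ALPHABET:
            m[x, y] = iupac_substitution_score(x, y)
    return m


@dataclass
class SubstitutionModel:
    """IUPAC substitution scores plus affine gap costs (open 10, extend 4)."""

    gap_open: float = 10.0
    gap_extend: float = 4.0
    matrix: substitution_matrices.Array = field(default_factory=_build_matrix)

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")

    def score(self, x: str, y: str) -> float:
        return float(self.matrix[x, y])


def _aligner(model: SubstitutionModel) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = model.matrix
    # a gap of length k costs open + k*extend: first gapped position
    # open+extend, each further position extend
    aligner.open_gap_score = -(model.gap_open + model.gap_extend)
    aligner.extend_gap_score = -model.gap_extend
    return aligner


def global_align_score(c1: str, c2: str, model: SubstitutionModel | None = None) -> float:
    """Optimal global alignment score of two IUPAC consensus strings."""
    validate_word(c1)
    validate_word(c2)
    model = model or SubstitutionModel()
    return float(_aligner(model).score(c1, c2))


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal motif-motif distance matrix with entries in [0, 1]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("motif\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def motif_distance_matrix(
    consensi: Sequence[str],
    model: SubstitutionModel | None = None,
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Min-max-normalized complement-to-1 distance over pairwise alignment scores.

    With fewer than two motifs there is nothing to normalize — error.
    When every off-diagonal pair scores identically, all distances are
    set to 0 with a warning (equal evidence of similarity should not
    fabricate separation).
    """
    n = len(consensi)
    if n < 2:
        raise ValueError(f"need at least 2 motifs to build a distance matrix, got {n}")
    model = model or SubstitutionModel()
    labels = list(labels) if labels is not None else [f"M{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels must parallel consensi")
    scores = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        s = global_align_score(consensi[i], consensi[j], model)
        scores[i, j] = scores[j, i] = s
    off = scores[~np.eye(n, dtype=bool)]
    s_min, s_max = off.min(), off.max()
    dist = np.zeros((n, n))
    if s_max == s_min:
        logger.warning(
            "all pairwise similarities are equal (%.4g); all distances set to 0", s_min
        )
    else:
        norm = (scores - s_min) / (s_max - s_min)
        dist = 1.0 - norm
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, 1.0)
    return DistanceMatrix(labels=labels, values=dist)


def _fmt(x: float) -> str:
    return format(x, "g")


def upgma_cluster(
    D: DistanceMatrix,
    leaf_annotations: Mapping[str, str] | None = None,
    linkage: str = "average",
) -> str:
    """Agglomerative clustering of the distance matrix to a Newick string.

    ``average`` linkage (UPGMA: the merge distance of two clusters is the
    arithmetic mean of all original leaf-pair distances between them)
    yields an ultrametric tree whose node height is merge distance / 2;
    ``complete`` and ``single`` use max/min instead.  Ties in the minimal
    distance are broken by the lexicographically smallest pair of cluster
    representatives (the smallest leaf label in each cluster), which makes
    the topology deterministic.  Leaf labels are suffixed with their
    annotation (e.g. methylation trend) as ``label|trend``.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"linkage must be average, complete or single, got {linkage!r}")
    leaf_annotations = leaf_annotations or {}
    n = len(D.labels)
    if n == 1:
        lab = D.labels[0]
        if lab in leaf_annotations:
            lab = f"{lab}|{leaf_annotations[lab]}"
        return lab + ";"
    reducer = {"average": np.mean, "complete": np.max, "single": np.min}[linkage]

    def leaf_name(i: int) -> str:
        lab = D.labels[i]
        if lab in leaf_annotations:
            lab = f"{lab}|{leaf_annotations[lab]}"
        return lab

    clusters: dict[int, dict] = {
        i: {"leaves": [i], "height": 0.0, "nwk": leaf_name(i), "rep": D.labels[i]}
        for i in range(n)
    }
    next_id = n
    while len(clusters) > 1:
        best_key = None
        best_pair = None
        for ia, ib in combinations(sorted(clusters), 2):
            ca, cb = clusters[ia], clusters[ib]
            d = float(
                reducer(D.values[np.ix_(ca["leaves"], cb["leaves"])])
            )
            key = (d, tuple(sorted((ca["rep"], cb["rep"]))))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (ia, ib)
        ia, ib = best_pair
        ca, cb = clusters.pop(ia), clusters.pop(ib)
        d = best_key[0]
        h = d / 2.0
        # child with the smaller representative label is written first
        first, second = sorted((ca, cb), key=lambda c: c["rep"])
        nwk = (
            f"({first['nwk']}:{_fmt(h - first['height'])},"
            f"{second['nwk']}:{_fmt(h - second['height'])})"
        )
        clusters[next_id] = {
            "leaves": ca["leaves"] + cb["leaves"],
            "height": h,
            "nwk": nwk,
            "rep": min(ca["rep"], cb["rep"]),
        }
        next_id += 1
    root = next(iter(clusters.values()))
    return root["nwk"] + ";"
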