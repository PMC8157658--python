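import math

import numpy as np
import pytest

from methylmotif.errors import DataError
from methylmotif.simulate import generate_pfm_db
from methylmotif.tfbs import (
    PFM,
    TFBSThresholds,
    bh_qvalues,
    column_score,
    compare_motifs,
    consensus_to_pfm,
    match_tfbs,
    occurrence_pfm,
    read_meme_motifs,
    write_meme_motifs,
)


class TestMemeFormat:
    def test_round_trip_preserves_widths_and_values(self, tmp_path):
        db = generate_pfm_db(2, seed=4)
        path = tmp_path / "db.meme"
        write_meme_motifs(db, path)
        back = read_meme_motifs(path)
        assert [p.width for p in back] == [p.width for p in db]
        for a, b in zip(db, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-7)
            assert (a.motif_id, a.tf_name) == (b.motif_id, b.tf_name)

    def test_bad_column_sum_names_motif_and_line(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF BADMOT tf1\n"
            "letter-probability matrix: alength= 4 w= 2\n"
            "0.25 0.25 0.25 0.25\n"
            "0.2 0.2 0.2 0.2\n"
        )
        with pytest.raises(DataError, match="BADMOT"):
            read_meme_motifs(path)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text(
            "MOTIF M1\n"
            "letter-probability matrix: alength= 4 w= 2\n"
            "0.25 0.25 0.25 0.25\n"
            "0.25 oops 0.25 0.25\n"
        )
        with pytest.raises(DataError, match=r":4:"):
            read_meme_motifs(path)

    def test_no_motif_blocks_is_empty_with_warning(self, tmp_path, caplog):
        import logging

        path = tmp_path / "none.meme"
        path.write_text("MEME version 4\nALPHABET= ACGT\n")
        with caplog.at_level(logging.WARNING):
            assert read_meme_motifs(path) == []
        assert any("no MOTIF" in r.message for r in caplog.records)


class TestConsensusToPFM:
    def test_concrete_bases(self):
        pfm = consensus_to_pfm("AC")
        assert np.allclose(pfm.matrix, [[1, 0, 0, 0], [0, 1, 0, 0]])

    def test_ambiguity_codes(self):
        assert np.allclose(consensus_to_pfm("N").matrix, [[0.25] * 4])
        assert np.allclose(consensus_to_pfm("W").matrix, [[0.5, 0, 0, 0.5]])

    def test_revcomp_swaps_and_reverses(self):
        pfm = consensus_to_pfm("AC")
        rc = pfm.revcomp()
        # revcomp of AC is GT
        assert np.allclose(rc.matrix, consensus_to_pfm("GT").matrix)

    def test_occurrence_pfm_reflects_realized_bases(self):
        seqs = ["CCTGAAAAACC"] * 5 + ["CCTGATAAACC"] * 5
        pfm = occurrence_pfm("TGAWAAA", seqs)
        # the W column splits evenly between A and T; concrete columns peak
        assert pfm.matrix[3, 0] == pytest.approx(pfm.matrix[3, 3])
        assert pfm.matrix[0, 3] > 0.9
        # no occurrences -> uniform consensus fallback
        assert np.allclose(
            occurrence_pfm("CCCCC", ["AAAA"]).matrix,
            consensus_to_pfm("CCCCC").matrix,
        )


class TestColumnScore:
    def test_identical_columns(self):
        assert column_score([0.25] * 4, [0.25] * 4) == pytest.approx(1.0)

    def test_maximally_distant_columns(self):
        assert column_score([1, 0, 0, 0], [0, 0, 0, 1]) == pytest.approx(0.0)

    def test_concrete_vs_uniform(self):
        expected = 1 - math.sqrt(0.75) / math.sqrt(2)
        assert column_score([1, 0, 0, 0], [0.25] * 4) == pytest.approx(expected)


class TestCompareMotifs:
    def test_self_match(self):
        q = consensus_to_pfm("TGAC")
        score, offset, orientation, overlap = compare_motifs(q, q, min_overlap=1)
        assert (score, offset, orientation, overlap) == (1.0, 0, "+", 4)

    def test_single_column_reverse_complement(self):
        a = consensus_to_pfm("A")
        t = consensus_to_pfm("T")
        score, offset, orientation, overlap = compare_motifs(a, t, min_overlap=1)
        assert score == pytest.approx(1.0) and orientation == "-"

    def test_min_overlap_unsatisfiable_is_sentinel(self):
        q = consensus_to_pfm("ACG")
        assert compare_motifs(q, q, min_overlap=5) is None

    def test_invalid_min_overlap(self):
        q = consensus_to_pfm("ACG")
        with pytest.raises(ValueError):
            compare_motifs(q, q, min_overlap=0)

    def test_score_invariant_under_query_reverse_complement(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            qm = rng.dirichlet([1] * 4, size=5)
            tm = rng.dirichlet([1] * 4, size=8)
            q = PFM("q", "q", qm)
            t = PFM("t", "t", tm)
            s1 = compare_motifs(q, t)[0]
            s2 = compare_motifs(q.revcomp(), t)[0]
            assert s1 == pytest.approx(s2)

    def test_overlap_bounded_by_widths(self):
        q = consensus_to_pfm("ACGTA")
        t = consensus_to_pfm("TTT")
        *_, overlap = compare_motifs(q, t, min_overlap=2)
        assert 2 <= overlap <= 3


class TestBHQvalues:
    def test_all_tied_step_up(self):
        assert bh_qvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_two_values(self):
        assert bh_qvalues([0.005, 0.1]) == pytest.approx([0.01, 0.1])

    def test_single_value_clamped(self):
        assert bh_qvalues([1.0]) == [1.0]

    def test_hand_step_up_oracle(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=9)
        m = len(p)
        order = np.argsort(p)
        q_sorted = [p[order[i]] * m / (i + 1) for i in range(m)]
        for i in range(m - 2, -1, -1):
            q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert bh_qvalues(p) == pytest.approx(list(expected))

    def test_qvalues_dominate_pvalues(self):
        rng = np.random.default_rng(3)
        p = list(rng.uniform(size=12))
        q = bh_qvalues(p)
        assert all(qi >= pi - 1e-12 for qi, pi in zip(q, p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.5])


@pytest.fixture(scope="module")
def db_with_query():
    query = consensus_to_pfm("TGAWAAA", motif_id="QUERY")
    return query, generate_pfm_db(10, seed=1, include_query=query)


class TestMatchTFBS:

    def test_embedded_query_ranks_first(self, db_with_query):
        query, db = db_with_query
        matches = match_tfbs(
            query, db, TFBSThresholds(p=1.0, e=100, q=1.0, overlap=1),
            n_null=300, seed=5,
        )
        assert matches[0].target_id == "QUERY"
        assert matches[0].score == pytest.approx(1.0)
        assert matches[0].pvalue == min(m.pvalue for m in matches)
        assert matches[0].pvalue == pytest.approx(1 / 301)

    def test_pvalues_within_monte_carlo_range_and_q_dominates(self, db_with_query):
        query, db = db_with_query
        matches = match_tfbs(
            query, db, TFBSThresholds(p=1.0, e=100, q=1.0, overlap=1),
            n_null=200, seed=5,
        )
        for m in matches:
            assert 1 / 201 <= m.pvalue <= 1.0
            assert m.evalue == pytest.approx(m.pvalue * len(db))
            assert m.qvalue >= m.pvalue - 1e-12
            assert m.overlap >= 1

    def test_same_seed_is_bit_identical(self, db_with_query):
        query, db = db_with_query
        kw = dict(thresholds=TFBSThresholds(p=1.0, e=100, q=1.0), n_null=100, seed=7)
        m1 = match_tfbs(query, db, **kw)
        m2 = match_tfbs(query, db, **kw)
        assert m1 == m2

    def test_filters_are_monotone(self, db_with_query):
        query, db = db_with_query
        loose = match_tfbs(query, db, TFBSThresholds(p=1.0, e=100, q=1.0), n_null=100, seed=3)
        tight = match_tfbs(query, db, TFBSThresholds(p=0.05, e=100, q=1.0), n_null=100, seed=3)
        assert len(tight) <= len(loose)
        assert {m.target_id for m in tight} <= {m.target_id for m in loose}

    def test_invalid_n_null(self, db_with_query):
        query, db = db_with_query
        with pytest.raises(ValueError):
            match_tfbs(query, db, n_null=0)

    def test_empty_db_rejected(self, db_with_query):
        query, _ = db_with_query
        with pytest.raises(ValueError):
            match_tfbs(query, [])
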