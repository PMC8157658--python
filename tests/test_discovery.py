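import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from conftest import fisher_oracle
from methylmotif.discovery import (
    DiscoveryParams,
    count_sequences_with_word,
    discover_motifs,
    erase_occurrences,
    evalue,
    fisher_exact_2x2,
    generalize_word,
    read_motif_tsv,
    write_motif_tsv,
)
from methylmotif.iupac import IUPAC_BASES, match_positions

counts = st.integers(min_value=0, max_value=12)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,alt,expected",
        [
            ((3, 1, 1, 3), "two_sided", 34 / 70),
            ((0, 5, 5, 0), "two_sided", 2 / 252),
            ((2, 2, 2, 2), "two_sided", 1.0),
            ((5, 0, 0, 5), "greater", 1 / 252),
            ((0, 5, 5, 0), "greater", 1.0),
        ],
    )
    def test_frozen_examples(self, table, alt, expected):
        assert fisher_exact_2x2(*table, alternative=alt) == pytest.approx(
            expected, abs=1e-15
        )

    def test_all_zero_table_is_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    @settings(max_examples=200, derandomize=True)
    @given(a=counts, b=counts, c=counts, d=counts)
    def test_agrees_with_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        for alt in ("greater", "two_sided"):
            assert fisher_exact_2x2(a, b, c, d, alt) == pytest.approx(
                fisher_oracle(a, b, c, d, alt), abs=1e-12
            )

    @settings(max_examples=100, derandomize=True)
    @given(a=counts, b=counts, c=counts, d=counts)
    def test_cross_checks_against_scipy(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact_2x2(a, b, c, d, "greater") == pytest.approx(
            fisher_exact([[a, b], [c, d]], alternative="greater")[1], abs=1e-9
        )
        assert fisher_exact_2x2(a, b, c, d, "two_sided") == pytest.approx(
            fisher_exact([[a, b], [c, d]], alternative="two-sided")[1], abs=1e-9
        )


class TestWordCountingAndEvalue:
    def test_sequence_level_counting(self):
        assert count_sequences_with_word("ACG", ["AACGTA", "TTTTTT", "TACGTT"]) == 2
        assert count_sequences_with_word("ACG", ["ACGACG"]) == 1
        assert count_sequences_with_word("ACG", []) == 0

    @pytest.mark.parametrize(
        "p,n,expected", [(0.001, 50, 0.05), (0.05, 1, 0.05), (1.0, 100, 100.0)]
    )
    def test_evalue_is_unclamped_product(self, p, n, expected):
        assert evalue(p, n) == pytest.approx(expected)

    def test_evalue_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            evalue(1.5, 10)
        with pytest.raises(ValueError):
            evalue(0.5, 0)


class TestErasure:
    def test_forward_only_occurrence(self):
        # ACG at offset 2; its reverse complement CGT is absent
        assert erase_occurrences(["AAACGAAA"], "ACG") == ["AANNNAAA"]

    def test_both_strand_union(self):
        # forward ACG at offset 1 and reverse-strand occurrence (CGT at 2)
        assert erase_occurrences(["AACGTA"], "ACG") == ["ANNNNA"]

    def test_no_match_is_identity(self):
        assert erase_occurrences(["TTTTTT"], "ACG") == ["TTTTTT"]

    def test_overlapping_matches_erase_union_of_positions(self):
        seqs = ["AAAAAA"]
        out = erase_occurrences(seqs, "AAA")
        covered = match_positions("AAAAAA", "AAA")
        expected = "".join("N" if i in covered else c for i, c in enumerate("AAAAAA"))
        assert out == [expected] == ["NNNNNN"]

    def test_lengths_preserved(self, small_flanks):
        targets, _ = small_flanks
        seqs = [f.seq for f in targets[:20]]
        erased = erase_occurrences(seqs, "TGAWAAA")
        assert [len(s) for s in erased] == [len(s) for s in seqs]


class TestGeneralization:
    def _fixture(self):
        # TGAAAAA and TGATAAA each enriched; the W-union strictly dominates
        pos = ["CC" + "TGAAAAA" + "CC"] * 10 + ["CC" + "TGATAAA" + "CC"] * 10
        neg = ["CCCCCCCCCCC"] * 20
        return pos, neg

    def test_union_word_dominates_seed(self):
        pos, neg = self._fixture()
        word, p, n_eval = generalize_word("TGAAAAA", pos, neg, beam_width=8)
        assert IUPAC_BASES[word[3]] >= {"A", "T"}  # position 4 generalized
        seed_p = fisher_exact_2x2(10, 10, 0, 20, "greater")
        assert p <= seed_p
        assert n_eval > 1

    def test_seed_returned_when_no_variant_helps(self):
        pos = ["CCTGAAAAACC"] * 10
        neg = ["CCCCCCCCCCC"] * 10
        word, p, _ = generalize_word("TGAAAAA", pos, neg, beam_width=8)
        assert word == "TGAAAAA"

    def test_invalid_beam_width(self):
        with pytest.raises(ValueError):
            generalize_word("ACG", ["ACG"], ["TTT"], beam_width=0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**16))
    def test_generalization_never_worsens_p(self, seed):
        rng = np.random.default_rng(seed)
        mk = lambda n: ["".join(rng.choice(list("ACGT"), 12)) for _ in range(n)]
        pos, neg = mk(15), mk(15)
        seed_word = pos[0][2:6]
        word, p, _ = generalize_word(seed_word, pos, neg, beam_width=4)
        a = count_sequences_with_word(seed_word, pos)
        c = count_sequences_with_word(seed_word, neg)
        seed_p = fisher_exact_2x2(a, 15 - a, c, 15 - c, "greater")
        assert p <= seed_p + 1e-12


class TestDiscoverMotifs:
    def test_no_signal_when_pos_equals_neg(self, small_flanks):
        targets, _ = small_flanks
        seqs = [f.seq for f in targets[:40]]
        assert discover_motifs(seqs, list(seqs)) == []

    def test_two_disjoint_planted_words(self):
        rng = np.random.default_rng(5)
        bg = lambda: "".join(rng.choice(list("ACGT"), 40))
        pos, neg = [], []
        for i in range(120):
            s = bg()
            if i % 3 == 0:
                s = s[:5] + "TGAGCGA" + s[12:]
            elif i % 3 == 1:
                s = s[:20] + "CATTCCG" + s[27:]
            pos.append(s)
            neg.append(bg())
        motifs = discover_motifs(pos, neg, DiscoveryParams(max_motifs=4))
        assert len(motifs) >= 2
        # erasure prevents rediscovery: consensus strings must differ
        assert len({m.consensus for m in motifs}) == len(motifs)
        ps = [m.pvalue for m in motifs]
        assert ps == sorted(ps)
        for m in motifs:
            assert m.pvalue <= 0.05 and m.evalue <= 0.05
            assert m.n_pos_with + m.n_pos_without == len(pos)
            assert m.evalue >= m.pvalue
            assert len(m.supporting_cpgs) == m.n_pos_with

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            discover_motifs([], ["ACGT"])

    def test_motif_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        bg = lambda: "".join(rng.choice(list("ACGT"), 40))
        pos = [s[:5] + "TGAGCGA" + s[12:] for s in (bg() for _ in range(60))]
        neg = [bg() for _ in range(60)]
        motifs = discover_motifs(pos, neg)
        assert motifs
        path = tmp_path / "motifs.tsv"
        write_motif_tsv(motifs, path)
        assert read_motif_tsv(path) == motifs
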