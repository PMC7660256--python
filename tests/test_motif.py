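"""Degenerate-palindrome scoring, rendering, scanning and matrices."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from regulonscan import (
    DegeneratePalindrome,
    build_matrix,
    derive_consensus,
    load_binding_sites,
    render_match,
    scan_window,
    score_against_box,
)
from regulonscan.motif import read_matrix, reverse_complement, write_matrix

seventeen_mers = st.text(alphabet="ACGT", min_size=17, max_size=17)


def brute_force_best(sequence, box):
    """Exhaustive best (matches, offset, strand) with the same tie order."""
    best = None
    for offset in range(len(sequence) - box.length + 1):
        window = sequence[offset:offset + box.length]
        for rank, site in enumerate((window, reverse_complement(window))):
            matches = sum(
                1
                for i in box.informative_positions
                if site[i].upper() == box.full_consensus[i]
            )
            key = (-matches, offset, rank)
            if best is None or key < best:
                best = key
    return -best[0], best[1], "+" if best[2] == 0 else "-"


class TestBox:
    def test_default_box_is_17bp_with_14_informative(self, box):
        assert box.full_consensus == "AATTGGTnnnACCAATT"
        assert box.length == 17
        assert box.n_informative == 14

    def test_full_consensus_is_its_own_reverse_complement(self, box):
        rc = reverse_complement(box.full_consensus.upper()).replace("N", "n")
        assert rc == box.full_consensus

    def test_short_box_variant_is_constructible(self):
        short = DegeneratePalindrome(arm="ATTGGT", spacer_length=3)
        assert short.length == 15
        assert short.n_informative == 12


class TestScoreAgainstBox:
    @pytest.mark.parametrize(
        "site,expected",
        [
            ("AATTGGTAAGACCAATT", 14),  # perfect site upstream of pdhR
            ("AATTGGTATAACCAATG", 13),  # cyoA site
            ("TCCTGGTCATAGCACCT", 8),   # fadE/lpcA site
            ("AATTGGTCCTACCTGTG", 11),  # glcD site
            ("CAGCGGTAAAACCTGAC", 7),   # fadI site, weakest printed
            ("CGTTAGCCACGCCAACA", 7),   # deoC-region site
            ("CCCCCCCAAAGGGGGGG", 0),
        ],
    )
    def test_known_sites(self, box, site, expected):
        score = score_against_box(site, box)
        assert score.matches == expected
        assert score.rendered == f"{expected}/14"

    def test_case_insensitive_and_spacer_never_scored(self, box):
        assert score_against_box("aattggtNNNaccaatt", box).matches == 14

    def test_ambiguity_codes_count_as_mismatch(self, box):
        assert score_against_box("NATTGGTAAGACCAATT", box).matches == 13
        assert score_against_box("RATTGGTAAGACCAATT", box).matches == 13

    def test_length_mismatch_is_error(self, box):
        with pytest.raises(ValueError, match="length"):
            score_against_box("AATTGGT", box)

    @given(site=seventeen_mers)
    def test_strand_symmetry_on_random_17mers(self, site):
        box = DegeneratePalindrome()
        fwd = score_against_box(site, box).matches
        rev = score_against_box(reverse_complement(site), box).matches
        assert fwd == rev

    @given(site=seventeen_mers, data=st.data())
    def test_single_mutation_monotonicity(self, site, data):
        box = DegeneratePalindrome()
        before = score_against_box(site, box).matches
        pos = data.draw(st.integers(min_value=0, max_value=16))
        base = data.draw(st.sampled_from([b for b in "ACGT" if b != site[pos]]))
        mutated = site[:pos] + base + site[pos + 1:]
        after = score_against_box(mutated, box).matches
        if pos not in box.informative_positions:
            assert after == before
        elif site[pos] == box.full_consensus[pos]:
            assert after == before - 1
        else:
            assert after >= before - 1


class TestRenderMatch:
    @pytest.mark.parametrize(
        "site,expected",
        [
            ("AATTGGTAAGACCAATT", "AATTGGTaagACCAATT"),
            ("AGTTGGTTATACCAAAG", "AgTTGGTtatACCAAag"),
            ("TCCTGGTCATAGCACCT", "tccTGGTcatAgCAccT"),
            ("CCCCCCCAAAGGGGGGG", "cccccccaaaggggggg"),
        ],
    )
    def test_casing_convention(self, box, site, expected):
        assert render_match(site, box) == expected

    @given(site=seventeen_mers)
    def test_uppercasing_round_trips(self, site):
        assert render_match(site).upper() == site


class TestScanWindow:
    def test_window_equal_to_box_matches_at_origin(self, box):
        m = scan_window("AATTGGTAAGACCAATT", box, origin=1)
        assert (m.genome_position, m.strand, m.score.matches) == (1, "+", 14)

    def test_planted_perfect_site_found_in_random_background(self, box, rng):
        background = "".join(rng.choice(list("ACGT"), size=500))
        planted = "AATTGGTAAGACCAATT"
        seq = background[:200] + planted + background[217:]
        m = scan_window(seq, box, origin=1)
        assert m.genome_position == 201
        assert m.score.matches == 14
        assert m.site_sequence == planted

    def test_reverse_complement_site_scores_on_minus_strand(self, box):
        site = "AATTGGTATAACCAATG"  # 13/14
        assert score_against_box(site, box).matches == 13
        seq = "CC" + reverse_complement(site) + "GG"
        m = scan_window(seq, box, origin=1)
        assert m.score.matches == 13
        assert m.genome_position == 3

    def test_too_short_window_rejected(self, box):
        with pytest.raises(ValueError, match="shorter than the box"):
            scan_window("ACGT", box)

    @given(
        seq=st.text(alphabet="ACGT", min_size=17, max_size=120),
        origin=st.integers(min_value=1, max_value=1000),
    )
    def test_equals_brute_force_on_short_windows(self, seq, origin):
        box = DegeneratePalindrome()
        m = scan_window(seq, box, origin=origin)
        matches, offset, strand = brute_force_best(seq, box)
        assert m.score.matches == matches
        assert m.genome_position == origin + offset
        assert m.strand == strand

    def test_brute_force_agreement_on_kb_scale_windows(self, box, rng):
        for _ in range(8):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            m = scan_window(seq, box)
            matches, offset, strand = brute_force_best(seq, box)
            assert (m.score.matches, m.genome_position, m.strand) == (
                matches, 1 + offset, strand,
            )


class TestMatrix:
    def test_identical_sites_give_two_bits_everywhere(self):
        matrix = build_matrix(["AATTGGTAAAACCAATT"] * 10, pseudocount=0)
        np.testing.assert_allclose(matrix.information_content, 2.0)

    def test_even_two_way_split_gives_one_bit(self):
        matrix = build_matrix(["AAAA", "CCCC"], pseudocount=0)
        np.testing.assert_allclose(matrix.information_content, 1.0)

    def test_column_sums_are_sites_plus_pseudocounts(self):
        matrix = build_matrix(["ACGT", "ACGG", "TCGA"], pseudocount=0.5)
        np.testing.assert_allclose(matrix.counts.sum(axis=1), 3 + 4 * 0.5)

    def test_ragged_sites_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            build_matrix(["ACGT", "ACG"])

    def test_palindrome_core_is_most_conserved_in_packaged_sites(self):
        df = load_binding_sites()
        seqs = [s.upper() for s in df.site_sequence.dropna()]
        matrix = build_matrix(seqs, pseudocount=0)
        freq = {
            i: matrix.probabilities[i, "ACGT".index(b)]
            for i, b in enumerate("AATTGGTNNNACCAATT")
            if b != "N"
        }
        # trinucleotide core GGT...ACC: 0-based positions 4-6 and 10-12
        core = {4, 5, 6, 10, 11, 12}
        core_mean = np.mean([f for i, f in freq.items() if i in core])
        flank_mean = np.mean([f for i, f in freq.items() if i not in core])
        assert core_mean > flank_mean

    def test_matrix_tsv_round_trip(self, tmp_path):
        matrix = build_matrix(["ACGT", "ACGG"], pseudocount=0.5)
        path = tmp_path / "m.tsv"
        write_matrix(matrix, path)
        back = read_matrix(path, pseudocount=0.5)
        np.testing.assert_allclose(back.counts, matrix.counts)


class TestDeriveConsensus:
    def test_unanimous_sites_reproduce_themselves(self):
        matrix = build_matrix(["AATTGGTAAAACCAATT"] * 10, pseudocount=0)
        assert derive_consensus(matrix, 0.8) == "AATTGGTAAAACCAATT"

    def test_even_split_position_becomes_n(self):
        matrix = build_matrix(["AAAA", "ACAA"], pseudocount=0)
        assert derive_consensus(matrix, 0.6) == "AnAA"

    def test_packaged_sites_recover_ggt_nnn_acc_core(self):
        df = load_binding_sites()
        seqs = [s.upper() for s in df.site_sequence.dropna()]
        consensus = derive_consensus(build_matrix(seqs), majority_threshold=0.75)
        assert consensus[4:7] == "GGT"
        assert consensus[10:13] == "ACC"

    def test_threshold_must_exceed_uniform(self):
        matrix = build_matrix(["ACGT"])
        with pytest.raises(ValueError, match="threshold"):
            derive_consensus(matrix, 0.2)
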