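"""Maximal exact match detection, intersection, and comparison counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hgtnet.match_core import (
    ComparisonCount,
    GenomeRecord,
    InputError,
    MatchRecord,
    count_comparisons,
    find_maximal_exact_matches,
    find_maximal_exact_matches_bruteforce,
    find_multimatches,
    intersect_to_multimatch,
    read_matches_tsv,
    write_matches_tsv,
)

from conftest import random_seq


def as_tuples(matches):
    return [(m.start_a, m.start_b, m.length) for m in matches]


class TestFindMems:
    def test_small_example(self):
        # expected set computed with the brute-force DP oracle:
        # ACGTACG at (0,2) and the internal repeat TACGTA at (3,1)
        ms = find_maximal_exact_matches("ACGTACGTAA", "TTACGTACGG", min_len=4)
        assert as_tuples(ms) == [(0, 2, 7), (3, 1, 6)]

    def test_identical_sequences(self, rng):
        s = random_seq(rng, 5000)
        ms = find_maximal_exact_matches(s, s, min_len=1000)
        assert as_tuples(ms) == [(0, 0, 5000)]

    def test_random_backgrounds_share_nothing_long(self, rng):
        a = random_seq(rng, 100_000)
        b = random_seq(rng, 100_000)
        assert find_maximal_exact_matches(a, b, min_len=1000) == []

    def test_genome_record_ids_propagate(self, rng):
        s = random_seq(rng, 200)
        ga = GenomeRecord("g1", "A", s)
        gb = GenomeRecord("g2", "B", s)
        ms = find_maximal_exact_matches(ga, gb, min_len=100)
        assert ms[0].genome_a == "g1" and ms[0].genome_b == "g2"

    def test_non_acgt_is_universal_mismatch(self):
        s = "ACGTNACGT"
        ms = find_maximal_exact_matches(s, s, min_len=4)
        # N terminates matches and does not even match itself; the repeated
        # ACGT contributes every occurrence pair
        assert as_tuples(ms) == [(0, 0, 4), (0, 5, 4), (5, 0, 4), (5, 5, 4)]

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_with_planted_blocks(self, seed):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, 1500)
        b = random_seq(rng, 1500)
        blk = random_seq(rng, 250)
        a = a[:400] + blk + a[650:]
        b = b[:900] + blk + b[1150:]
        got = find_maximal_exact_matches(a, b, min_len=9)
        expected = find_maximal_exact_matches_bruteforce(a, b, min_len=9)
        assert got == expected and len(got) >= 1

    @pytest.mark.parametrize("seed", range(4))
    def test_maximality_and_symmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = random_seq(rng, 3000)
        blk = random_seq(rng, 400)
        b = random_seq(rng, 1000) + blk + random_seq(rng, 1000)
        a = a[:700] + blk + a[1100:]
        ms = find_maximal_exact_matches(a, b, min_len=30)
        assert ms
        for m in ms:
            assert a[m.start_a : m.start_a + m.length] == b[m.start_b : m.start_b + m.length]
            if m.start_a > 0 and m.start_b > 0:
                assert a[m.start_a - 1] != b[m.start_b - 1]
            ea, eb = m.start_a + m.length, m.start_b + m.length
            if ea < len(a) and eb < len(b):
                assert a[ea] != b[eb]
        swapped = find_maximal_exact_matches(b, a, min_len=30)
        assert {(m.start_a, m.start_b, m.length) for m in ms} == {
            (m.start_b, m.start_a, m.length) for m in swapped
        }

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        a=st.text(alphabet="ACGT", min_size=4, max_size=60),
        b=st.text(alphabet="ACGT", min_size=4, max_size=60),
    )
    def test_matches_agree_with_oracle_on_tiny_strings(self, a, b):
        got = find_maximal_exact_matches(a, b, min_len=4)
        assert got == find_maximal_exact_matches_bruteforce(a, b, min_len=4)

    def test_input_errors(self):
        with pytest.raises(InputError):
            find_maximal_exact_matches("ACGT", "ACGT", min_len=1)
        with pytest.raises(InputError):
            find_maximal_exact_matches("", "ACGT", min_len=4)


def mk(start_a, length, gb="b1"):
    return MatchRecord("ref", gb, start_a, 0, length)


class TestIntersect:
    def test_two_partner_overlap(self):
        mm = intersect_to_multimatch(
            {"B": [mk(100, 500)], "C": [mk(300, 600, "c1")]}, min_len=200, ref_genus="A"
        )
        assert [(m.ref_start, m.ref_end, m.length) for m in mm] == [(300, 600, 300)]
        assert mm[0].genus_set == ("A", "B", "C")

    def test_disjoint_gives_nothing(self):
        mm = intersect_to_multimatch(
            {"B": [mk(0, 500)], "C": [mk(600, 300, "c1")]}, min_len=100, ref_genus="A"
        )
        assert mm == []

    def test_split_intervals(self):
        mm = intersect_to_multimatch(
            {"B": [mk(0, 400), mk(450, 550)], "C": [mk(200, 600, "c1")]},
            min_len=100,
            ref_genus="A",
        )
        assert [(m.ref_start, m.ref_end) for m in mm] == [(200, 400), (450, 800)]

    def test_mismatched_reference_error(self):
        bad = MatchRecord("other", "b1", 0, 0, 500)
        with pytest.raises(InputError):
            intersect_to_multimatch({"B": [mk(0, 500)], "C": [bad]}, 100, "A")

    def test_intersection_soundness_on_sequences(self):
        # Plant one segment shared by three genera; the intersected interval's
        # reference substring must occur verbatim in every partner genome.
        rng = np.random.default_rng(7)
        core = random_seq(rng, 800)
        ref = random_seq(rng, 2000) + core + random_seq(rng, 2000)
        b = random_seq(rng, 500) + core[:600] + random_seq(rng, 500)
        c = random_seq(rng, 300) + core[200:800] + random_seq(rng, 700)
        genomes = [
            GenomeRecord("r1", "A", ref),
            GenomeRecord("b1", "B", b),
            GenomeRecord("c1", "C", c),
        ]
        mms = find_multimatches(genomes, ("A", "B", "C"), min_len=100)
        assert len(mms) == 1
        m = mms[0]
        assert m.length == 400  # overlap of core[:600] and core[200:800]
        sub = ref[m.ref_start : m.ref_end]
        assert sub in b and sub in c


class TestComparisons:
    @pytest.mark.parametrize(
        "counts,total",
        [((3, 4), 12), ((1, 1, 1), 1), ((2,) * 8, 256)],
    )
    def test_product(self, counts, total, rng):
        genera = [f"G{i}" for i in range(len(counts))]
        coll = [
            GenomeRecord(f"{g}_{j}", g, random_seq(rng, 10))
            for g, k in zip(genera, counts)
            for j in range(k)
        ]
        cc = count_comparisons(coll, genera)
        assert cc.counts == counts and cc.total == total

    def test_missing_genus(self, rng):
        coll = [GenomeRecord("x", "A", random_seq(rng, 10))]
        with pytest.raises(InputError):
            count_comparisons(coll, ("A", "B"))


def test_match_tsv_roundtrip(tmp_path, rng):
    ms = [MatchRecord("g1", "g2", 5, 17, 1200), MatchRecord("g1", "g3", 0, 3, 2500)]
    p = tmp_path / "m.tsv"
    write_matches_tsv(ms, p)
    assert read_matches_tsv(p) == ms
    write_matches_tsv(ms, p, one_based=True)
    shifted = read_matches_tsv(p)
    assert shifted[0].start_a == 6 and shifted[0].start_b == 18
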