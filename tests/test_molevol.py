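"""NG86 counting, Jukes-Cantor correction and partitioned dN/dS."""

import math
from itertools import permutations

import numpy as np
import pytest
from Bio.Seq import Seq

from aedsx.molevol import (
    CodonAlignment,
    MolEvolError,
    SaturationError,
    aligned_identity,
    all_pairs,
    count_differences,
    count_sites,
    jc_correct,
    load_codon_alignment,
    pairwise_ng86,
    partition_summary,
)

SENSE = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
]


def translate(codon):
    return str(Seq(codon).translate())


def oracle_sites(codon, exclude_stops=True):
    """Independent literal transcription of the per-position site count."""
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if translate(mutant) == "*":
                if not exclude_stops:
                    tot += 1
                continue
            tot += 1
            if translate(mutant) == translate(codon):
                syn += 1
        if tot:
            s += syn / tot
    return s, 3 - s


def oracle_differences(a, b):
    """Independent pathway enumeration of (sd, nd)."""
    diff = [i for i in range(3) if a[i] != b[i]]
    outcomes = []
    for order in permutations(diff):
        current = a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            if translate(nxt) == "*":
                through_stop = True
                break
            if translate(nxt) == translate(current):
                sd += 1
            else:
                nd += 1
            current = nxt
        if not through_stop:
            outcomes.append((sd, nd))
    if not outcomes:
        return None  # all paths through stops; implementation falls back
    return (
        sum(o[0] for o in outcomes) / len(outcomes),
        sum(o[1] for o in outcomes) / len(outcomes),
    )


class TestCountSites:
    def test_phe_third_position_only(self):
        s, n = count_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_met_fully_nonsynonymous(self):
        assert count_sites("ATG") == (0.0, 3.0)

    @pytest.mark.parametrize("codon", SENSE)
    def test_all_sense_codons_match_enumeration(self, codon):
        s, n = count_sites(codon)
        es, en = oracle_sites(codon)
        assert s == pytest.approx(es)
        assert n == pytest.approx(en)

    @pytest.mark.parametrize("codon", SENSE)
    def test_strict_denominator_variant(self, codon):
        s, n = count_sites(codon, exclude_stops=False)
        es, en = oracle_sites(codon, exclude_stops=False)
        assert s == pytest.approx(es)
        assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(MolEvolError, match="stop"):
            count_sites("TAA")


class TestCountDifferences:
    def test_single_synonymous_step(self):
        assert count_differences("TTT", "TTC") == (1.0, 0.0)

    def test_identical_codons(self):
        assert count_differences("AAA", "AAA") == (0.0, 0.0)

    def test_two_path_average_matches_oracle(self):
        got = count_differences("TTT", "GTA")
        expected = oracle_differences("TTT", "GTA")
        assert got == pytest.approx(expected)

    def test_random_pairs_match_path_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            a, b = rng.choice(SENSE, size=2)
            expected = oracle_differences(a, b)
            got = count_differences(a, b)
            if expected is not None:
                assert got == pytest.approx(expected), (a, b)
            k = sum(x != y for x, y in zip(a, b))
            assert got[0] + got[1] == pytest.approx(k)


class TestJukesCantor:
    def test_boundary_values(self):
        assert jc_correct(0.0) == 0.0
        assert jc_correct(0.1) == pytest.approx(0.10732, abs=1e-5)
        with pytest.raises(SaturationError):
            jc_correct(0.75)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 0.7, 50)
        values = [jc_correct(p) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestPairwise:
    def test_identical_sequences_ds_zero_status(self):
        seq = "ATGTTTGGGCCC"
        rates = pairwise_ng86(seq, seq)
        assert rates.Sd == rates.Nd == 0
        assert rates.status == "dS_zero"

    def test_symmetry(self):
        a = "ATGTTTGGGCCCAAATTGCATGAT"
        b = "ATGTTCGGACCCAGATTGCACGAC"
        ab = pairwise_ng86(a, b)
        ba = pairwise_ng86(b, a)
        for attr in ("S", "N", "Sd", "Nd", "pS", "pN", "dS", "dN"):
            assert getattr(ab, attr) == pytest.approx(getattr(ba, attr))

    def test_site_sum_identity(self):
        """S + N equals 3x the compared codon count."""
        a = "ATGTTTGGGCCCAAATTGCATGAT"
        b = "ATGTTCGGACCCAGATTGCACGAC"
        rates = pairwise_ng86(a, b)
        assert rates.S + rates.N == pytest.approx(3 * rates.n_codons)

    def test_difference_sum_equals_raw_mismatches(self):
        rng = np.random.default_rng(41)
        a = "".join(rng.choice(SENSE, size=20))
        b = "".join(rng.choice(SENSE, size=20))
        rates = pairwise_ng86(a, b)
        raw = sum(
            x != y
            for ca, cb in zip(
                [a[i:i + 3] for i in range(0, 60, 3)],
                [b[i:i + 3] for i in range(0, 60, 3)],
            )
            for x, y in zip(ca, cb)
        )
        assert rates.Sd + rates.Nd == pytest.approx(raw)

    def test_twenty_codon_toy_matches_literal_oracle(self):
        """(S, N, Sd, Nd) on a 20-codon pair equal an independent literal
        transcription of the counting rules."""
        rng = np.random.default_rng(99)
        a_codons = list(rng.choice(SENSE, size=20))
        b_codons = list(rng.choice(SENSE, size=20))
        rates = pairwise_ng86("".join(a_codons), "".join(b_codons))
        S = sum(oracle_sites(ca)[0] + oracle_sites(cb)[0]
                for ca, cb in zip(a_codons, b_codons)) / 2
        Sd = Nd = 0.0
        for ca, cb in zip(a_codons, b_codons):
            o = oracle_differences(ca, cb)
            if o is None:
                continue  # none in this fixture
            Sd += o[0]
            Nd += o[1]
        assert rates.S == pytest.approx(S)
        assert rates.Sd == pytest.approx(Sd)
        assert rates.Nd == pytest.approx(Nd)

    def test_gap_and_n_codons_dropped_pairwise(self):
        a = "ATG---TTTNNN"
        b = "ATGAAATTCCCC"
        rates = pairwise_ng86(a, b)
        assert rates.n_codons == 2  # ATG and TTT/TTC only

    def test_gap_must_occupy_whole_codon(self):
        with pytest.raises(MolEvolError, match="partial-codon"):
            CodonAlignment(ids=["x", "y"], seqs=["ATGA-ATTT", "ATGAAATTT"])


class TestPartitions:
    def test_whole_alignment_partition_equals_no_partition(self):
        aln = CodonAlignment(
            ids=["a", "b", "c"],
            seqs=["ATGTTTGGGCCC", "ATGTTCGGACCC", "ATGTTAGGTCCA"],
        )
        whole = partition_summary(aln, {"all": [(1, 12)]})
        default = partition_summary(aln, {"all": None})
        assert whole[0].mean_ratio == default[0].mean_ratio

    def test_identical_sequences_full_exclusion(self):
        aln = CodonAlignment(ids=["a", "b"], seqs=["ATGTTT"] * 2)
        (summary,) = partition_summary(aln, {"all": None})
        assert summary.n_pairs == 0
        assert summary.n_excluded == 1
        assert summary.classification == "undetermined"

    def test_misframed_partition_rejected(self):
        aln = CodonAlignment(ids=["a", "b"],
                             seqs=["ATGTTTGGG", "ATGTTCGGA"])
        with pytest.raises(MolEvolError, match="frame"):
            partition_summary(aln, {"bad": [(2, 7)]})


class TestAlignmentIO:
    def test_fasta_round_trip(self, tmp_path):
        path = tmp_path / "aln.fa"
        path.write_text(">s1\nATGTTTGGG\n>s2\nATGTTCGGA\n")
        aln = load_codon_alignment(path)
        assert aln.ids == ["s1", "s2"]
        assert aln.n_codons == 3

    def test_unequal_lengths_rejected(self, tmp_path):
        path = tmp_path / "aln.fa"
        path.write_text(">s1\nATGTTT\n>s2\nATG\n")
        with pytest.raises(MolEvolError, match="unequal"):
            load_codon_alignment(path)


class TestAlignedIdentity:
    def test_published_est_identity(self):
        percent, reported = aligned_identity(166, 282)
        assert percent == pytest.approx(58.865, abs=1e-3)
        assert reported == 59

    @pytest.mark.parametrize(
        "identical, aligned, expected", [(0, 100, 0), (100, 100, 100)]
    )
    def test_bounds(self, identical, aligned, expected):
        assert aligned_identity(identical, aligned)[1] == expected

    def test_invalid_counts(self):
        with pytest.raises(MolEvolError):
            aligned_identity(5, 0)
        with pytest.raises(MolEvolError):
            aligned_identity(10, 5)
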