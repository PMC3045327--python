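"""IUPAC motif scanning, purine runs and bipartite region summaries."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from aedsx.motifs import (
    DEFAULT_CATALOGUE,
    MotifDefinition,
    MotifError,
    RegionAnnotation,
    cluster_hits,
    detect_purine_runs,
    expand_iupac,
    expected_chance_hits,
    load_catalogue,
    scan,
    summarize_regions,
)
from aedsx.splice import IUPAC_SETS
from aedsx.genemodel import reverse_complement


def naive_scan(seq, motif, max_mismatch):
    """Independent O(n*m) sliding-window oracle."""
    seq = seq.upper()
    m = len(motif.iupac)
    hits = []
    for i in range(len(seq) - m + 1):
        mism = sum(
            1 for j, code in enumerate(motif.iupac.upper())
            if seq[i + j] not in IUPAC_SETS[code]
        )
        if mism <= max_mismatch:
            hits.append((i, mism))
    return hits


class TestCatalogue:
    def test_bundled_catalogue_shapes(self):
        by_name = {m.name: m for m in DEFAULT_CATALOGUE}
        assert len(by_name) == 5
        assert len(by_name["dsxRE"]) == 13
        assert len(by_name["NvdsxRE"]) == 8
        assert len(by_name["RBP1_A"]) == 9
        assert len(by_name["RBP1_B"]) == 7
        assert len(by_name["TRA2_ISS"]) == 5

    def test_json_round_trip_and_duplicate_rejection(self, tmp_path):
        path = tmp_path / "cat.json"
        entries = [
            {"name": m.name, "iupac": m.iupac, "class": m.element_class}
            for m in DEFAULT_CATALOGUE
        ]
        path.write_text(json.dumps(entries))
        assert [m.name for m in load_catalogue(path)] == [
            m.name for m in DEFAULT_CATALOGUE
        ]
        path.write_text(json.dumps(entries + [entries[0]]))
        with pytest.raises(MotifError, match="duplicate"):
            load_catalogue(path)

    def test_invalid_code_rejected(self):
        with pytest.raises(MotifError, match="invalid IUPAC"):
            MotifDefinition("bad", "ACJ")

    def test_empty_catalogue_warns(self, tmp_path):
        path = tmp_path / "cat.json"
        path.write_text("[]")
        with pytest.warns(UserWarning):
            assert load_catalogue(path) == []


class TestExpandIupac:
    def test_nvdsxre_expands_to_four_words(self):
        words = expand_iupac(MotifDefinition("NvdsxRE", "KGAAGATW"))
        assert words == {"TGAAGATT", "TGAAGATA", "GGAAGATT", "GGAAGATA"}

    def test_tra2_iss_two_words(self):
        assert expand_iupac(MotifDefinition("iss", "CAAGR")) == {
            "CAAGA", "CAAGG"
        }

    def test_all_n_trimer_and_cap(self):
        assert len(expand_iupac(MotifDefinition("n3", "NNN"))) == 64
        with pytest.raises(MotifError, match="cap"):
            expand_iupac(MotifDefinition("n9", "N" * 9), cap=4096)


class TestScan:
    def test_planted_motif_found_exactly(self):
        rng = np.random.default_rng(0)
        seq = list(rng.choice(list("ACGT"), size=50))
        word = "TCATCAATCAACA"
        seq[10:10 + len(word)] = word
        seq = "".join(seq)
        motif = MotifDefinition("dsxRE", "TCWWCAATCAACA")
        hits = scan(seq, [motif])
        assert {(h.start, h.mismatches) for h in hits} == set(
            naive_scan(seq, motif, 0)
        )
        assert any(h.start == 10 for h in hits)

    def test_mismatch_budget(self):
        seq = "G" * 10 + "TCATCAATCATCA" + "G" * 10  # one base mutated
        motif = MotifDefinition("dsxRE", "TCWWCAATCAACA")
        assert scan(seq, [motif], max_mismatch=0) == []
        hits = scan(seq, [motif], max_mismatch=1)
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_motif_longer_than_sequence_yields_no_hits(self):
        assert scan("ACG", [MotifDefinition("m", "ACGTACGT")]) == []

    @settings(derandomize=True, max_examples=150)
    @given(
        seq=st.text(alphabet="ACGT", min_size=5, max_size=60),
        iupac=st.text(alphabet="ACGTRYSWKMN", min_size=2, max_size=8),
        k=st.integers(min_value=0, max_value=2),
    )
    def test_equals_naive_oracle(self, seq, iupac, k):
        motif = MotifDefinition("m", iupac)
        got = {(h.start, h.mismatches) for h in scan(seq, [motif],
                                                     max_mismatch=k)}
        assert got == set(naive_scan(seq, motif, k))

    def test_reverse_strand_symmetry(self):
        """Forward hits on a sequence equal reverse hits on its complement."""
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        motif = MotifDefinition("iss", "CAAGR")
        fwd = scan(seq, [motif], strands="forward")
        both_rc = scan(reverse_complement(seq), [motif], strands="both")
        rev_hits = [h for h in both_rc if h.strand == "-"]
        assert len(fwd) == len(rev_hits)
        assert {len(seq) - h.end for h in rev_hits} == {h.start for h in fwd}


class TestPurineRuns:
    def test_embedded_run(self):
        runs = detect_purine_runs("CCAAGAAGAAGAAACC", min_len=10)
        assert len(runs) == 1
        assert (runs[0].start, runs[0].end) == (2, 14)
        assert runs[0].purine_fraction == 1.0

    def test_all_pyrimidine_empty(self):
        assert detect_purine_runs("CTCTCTCTCTCTCTCT", min_len=4) == []

    def test_matches_brute_force_maximal_runs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            got = [(r.start, r.end) for r in detect_purine_runs(seq, min_len=5)]
            # brute force: maximal stretches of A/G
            expected = []
            i = 0
            while i < len(seq):
                if seq[i] in "AG":
                    j = i
                    while j < len(seq) and seq[j] in "AG":
                        j += 1
                    if j - i >= 5:
                        expected.append((i, j))
                    i = j
                else:
                    i += 1
            assert got == expected

    def test_fractional_windows_merge(self):
        seq = "AGAGTGAGAG" + "C" * 20
        runs = detect_purine_runs(seq, min_len=5, min_frac=0.8)
        assert len(runs) == 1
        assert runs[0].start == 0
        assert runs[0].purine_fraction >= 0.8


class TestRegionSummary:
    REGIONS = RegionAnnotation((("exon5a", 0, 500), ("exon5b", 500, 1000)))

    def _planted(self, n_a, n_b, seed=1):
        from aedsx.simulate import Planting, plant_motifs

        motif = {m.name: m for m in DEFAULT_CATALOGUE}["NvdsxRE"]
        seq = "C" * 1000  # pyrimidine background: no chance NvdsxRE hits
        plantings = []
        if n_a:
            plantings.append(Planting(motif, region=(0, 500), count=n_a))
        if n_b:
            plantings.append(Planting(motif, region=(500, 1000), count=n_b))
        seq, _ = plant_motifs(seq, plantings, seed=seed)
        hits = scan(seq, [motif], regions=self.REGIONS)
        return hits

    def test_planted_counts_and_chance_expectation(self):
        hits = self._planted(4, 0)
        summary = summarize_regions(hits, [], self.REGIONS, "exon5a", "exon5b")
        assert summary.counts.loc["NvdsxRE", "exon5a"] == 4
        assert summary.counts.loc["NvdsxRE", "exon5b"] == 0
        # 8-nt motif of degeneracy 4 in 500 nt: 493 * 4 / 4^8
        assert summary.expected.loc["NvdsxRE", "exon5a"] == pytest.approx(
            493 * 4 / 4 ** 8
        )

    def test_no_hits_p_value_one(self):
        summary = summarize_regions([], [], self.REGIONS, "exon5a", "exon5b")
        assert (summary.counts.values == 0).all()
        assert summary.p_values["NvdsxRE"] == pytest.approx(1.0)

    def test_exact_test_equals_hypergeometric_enumeration(self):
        """Fisher p for a one-sided planted split equals the two-sided
        hypergeometric enumeration computed independently."""
        hits = self._planted(5, 0)
        summary = summarize_regions(hits, [], self.REGIONS, "exon5a", "exon5b")
        m = 8
        pos = 500 - m + 1
        # enumeration: all tables with fixed margins, p-mass <= observed
        total_hits, total_pos = 5, 2 * pos
        rv = hypergeom(total_pos, total_hits, pos)
        p_obs = rv.pmf(5)
        expected_p = sum(
            rv.pmf(k) for k in range(6) if rv.pmf(k) <= p_obs * (1 + 1e-9)
        )
        assert summary.p_values["NvdsxRE"] == pytest.approx(expected_p)

    def test_missing_region_rejected(self):
        with pytest.raises(MotifError, match="not annotated"):
            summarize_regions([], [], self.REGIONS, "exon5a", "nowhere")

    def test_total_hits_partition_across_regions(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        motif = MotifDefinition("iss", "CAAGR")
        hits = scan(seq, [motif], regions=self.REGIONS)
        summary = summarize_regions(hits, [], self.REGIONS,
                                    "exon5a", "exon5b", [motif])
        labeled = int(summary.counts.loc["iss"].sum())
        unlabeled = sum(1 for h in hits if h.region_label is None)
        assert labeled + unlabeled == len(hits)


def test_cluster_hits_groups_by_gap():
    from aedsx.motifs import MotifHit

    def hit(start):
        return MotifHit("m", "c", start, start + 5, "+", "AAAAA", 0)

    clusters = cluster_hits([hit(0), hit(30), hit(200), hit(220)], gap=50)
    assert [len(c) for c in clusters] == [2, 2]


def test_chance_hit_expectation_matches_empirical_mean():
    """Closed-form chance-hit expectation within 3 SE of the empirical
    mean over 200 seeded random sequences."""
    motif = {m.name: m for m in DEFAULT_CATALOGUE}["TRA2_ISS"]
    length = 2000
    n_seeds = 200
    counts = []
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        seq = "".join(rng.choice(list("ACGT"), size=length))
        counts.append(len(scan(seq, [motif])))
    expected = expected_chance_hits(motif, length)
    total = sum(counts)
    # hit counts are near-Poisson; SE of the total ~ sqrt(expected total)
    assert abs(total - n_seeds * expected) < 3 * math.sqrt(n_seeds * expected)
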