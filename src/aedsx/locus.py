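"""Published junction table and comparison figures for the Aedes aegypti
doublesex (Aeadsx) locus on supercontig 1.370.

These are the desk inputs of the analyses: exon/intron sizes and the
donor/acceptor junction windows of the eight annotated exons, the
genome-wide acceptor consensus (8.02 +/- 2.15 pyrimidines over 4688
introns), the Anopheles gambiae comparison figures, and the microsynteny
gene counts for the dsx-containing regions of the two mosquitoes.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class JunctionRow:
    """One intron's junctions, keyed by the transcriptionally upstream exon."""

    exon_id: str
    exon_size: int
    exon_class: str
    donor_exonic: str      # last 6 exon nt
    donor_intronic: str    # first 16 intron nt
    intron_size: int
    acceptor_intronic: str  # last 16 intron nt (ends at the terminal dinucleotide)
    acceptor_exonic: str    # first 6 nt of the following exon


AEADSX_JUNCTIONS: tuple[JunctionRow, ...] = (
    JunctionRow("2", 518, "common",
                "TTGCAG", "gtaggtgtgaggcata", 274879,
                "tctcctctcttttcag", "GCAACC"),
    JunctionRow("3a", 45, "common",
                "TACCAG", "gtgagttcgctgttga", 43797,
                "tctcttctggtttcag", "TTGGCC"),
    JunctionRow("3b", 48, "common",
                "GAACAG", "gtgcgtacttccttaa", 85670,
                "tcgtttccaatttcag", "ACGACG"),
    JunctionRow("4", 135, "common",
                "ACGAAG", "gtatgggggttcttac", 13860,
                "cttctctgcctcgcag", "GTCAAG"),
    JunctionRow("5a", 461, "female_specific",
                "gttgag", "gtcattataagcttcc", 208,
                "acataatgaccacagt", "GCAAAT"),
    JunctionRow("5b", 465, "female_specific",
                "cgacag", "gtactgctattggagg", 10392,
                "tcaatccctcaaacag", "GATACG"),
    JunctionRow("6", 1063, "male_specific",
                "acgaag", "gtgagtgttctttttt", 22437,
                "ctcttttcttcaacag", "tttcac"),
)

# terminal exon (3' UTR); closes the gene but heads no intron
TERMINAL_EXON = ("7", 449, "utr")

EXON_SIZES: tuple[int, ...] = tuple(
    r.exon_size for r in AEADSX_JUNCTIONS
) + (TERMINAL_EXON[1],)
INTRON_SIZES: tuple[int, ...] = tuple(r.intron_size for r in AEADSX_JUNCTIONS)

# genome-wide 3' acceptor consensus, tabulated from 4688 Ae. aegypti introns
CONSENSUS_MEAN_Y = 8.02
CONSENSUS_SD_Y = 2.15
CONSENSUS_N_INTRONS = 4688

# Anopheles gambiae dsx region for the span comparison (85 kb, mean intron 15 kb)
ANOPHELES_DSX_REGION_BP = 85_000

# microsynteny of the dsx-containing regions: 10 conserved homologues,
# 16 genes total in the two regions
SYNTENY_CONSERVED_PAIRS = 10
SYNTENY_TOTAL_GENES = 16

# EST identity that anchored the cloning: 166 identical of 282 aligned nt
EST_IDENTICAL = 166
EST_ALIGNED = 282
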