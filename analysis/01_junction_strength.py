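#!/usr/bin/env python
"""Score the published exon-intron junctions of the Aedes aegypti
doublesex gene and call weak splice sites.

Finding: the acceptor preceding the female-specific exon 5b carries only
5 pyrimidines over the 12 Y-consensus positions and a GT (not AG)
terminus, and the exon-5b donor matches GTRAGT at only 3 of 6 positions;
both classify weak against the genome consensus 8.02 +/- 2.15, while all
other junctions classify strong.
"""

from pathlib import Path

import pandas as pd

from aedsx.genemodel import ExonRecord, GeneModel, summarize_gene
from aedsx.locus import (AEADSX_JUNCTIONS, CONSENSUS_MEAN_Y, CONSENSUS_SD_Y,
                         CONSENSUS_N_INTRONS, EXON_SIZES, INTRON_SIZES,
                         TERMINAL_EXON)
from aedsx.splice import (ConsensusStats, classify_acceptor, classify_donor,
                          score_acceptor, score_donor)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    stats = ConsensusStats(n_introns=CONSENSUS_N_INTRONS,
                           mean_y=CONSENSUS_MEAN_Y, sd_y=CONSENSUS_SD_Y)
    rows = []
    for row in AEADSX_JUNCTIONS:
        acceptor = score_acceptor(row.acceptor_intronic)
        donor = score_donor(row.donor_intronic[:6])
        a_call = classify_acceptor(row.exon_id, acceptor, stats)
        d_call = classify_donor(row.exon_id, donor)
        rows.append({
            "exon_id": row.exon_id,
            "exon_size": row.exon_size,
            "intron_size": row.intron_size,
            "donor_window": row.donor_intronic[:6],
            "donor_match": donor.match_count,
            "donor_weak": d_call.weak,
            "acceptor_window": row.acceptor_intronic,
            "y_count": acceptor.y_count,
            "acceptor_terminal": acceptor.terminal_dinucleotide,
            "acceptor_weak": a_call.weak,
            "weak_reasons": ";".join(a_call.reasons + d_call.reasons),
        })
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "junction_strength.tsv"
    table.to_csv(out, sep="\t", index=False)

    pos, exons = 0, []
    classes = [r.exon_class for r in AEADSX_JUNCTIONS] + [TERMINAL_EXON[2]]
    for i, size in enumerate(EXON_SIZES):
        exons.append(ExonRecord(f"e{i}", pos, pos + size, "+", classes[i]))
        pos += size + (INTRON_SIZES[i] if i < len(INTRON_SIZES) else 0)
    summary = summarize_gene(GeneModel("Aeadsx", "supercontig_1.370", "+",
                                       exons))

    print(table[["exon_id", "y_count", "acceptor_terminal", "donor_match",
                 "acceptor_weak", "donor_weak"]].to_string(index=False))
    print(f"\nY counts: {table['y_count'].tolist()}")
    print(f"weak sites: {int(table['acceptor_weak'].sum())} acceptor(s), "
          f"{int(table['donor_weak'].sum())} donor(s) - both flank exon 5b")
    print(f"gene span {summary.span_bp} bp; introns "
          f"{summary.intron_min_bp}-{summary.intron_max_bp} bp, "
          f"mean {summary.intron_mean_bp:.0f} bp "
          f"(~{summary.intron_mean_kb} kb)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
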