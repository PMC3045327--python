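#!/usr/bin/env python
"""Bipartite cis-element distribution across two female-specific exons.

Plants the catalogue elements in the layout reported for the regulated
doublesex region - NvdsxRE clustered in the "strong" exon 5a, TRA/TRA-2
binding sites (dsxRE) only in the "weak" exon 5b, TRA-2-ISS upstream -
then scans blind and quantifies the split with per-motif exact tests.
"""

from pathlib import Path

import numpy as np

from aedsx.motifs import (DEFAULT_CATALOGUE, RegionAnnotation,
                          detect_purine_runs, scan, summarize_regions)
from aedsx.simulate import Planting, plant_motifs

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rng = np.random.default_rng(71)
    # intron5a | exon5a (461 nt) | intron5 (208 nt) | exon5b (465 nt)
    layout = RegionAnnotation((
        ("upstream_intron", 0, 400),
        ("exon5a", 400, 861),
        ("intron5", 861, 1069),
        ("exon5b", 1069, 1534),
    ))
    background = "".join(rng.choice(list("ACGT"), size=1534))
    by_name = {m.name: m for m in DEFAULT_CATALOGUE}
    plantings = [
        Planting(by_name["NvdsxRE"], region=(400, 861), count=4),
        Planting(by_name["NvdsxRE"], region=(861, 1069), count=1),
        Planting(by_name["TRA2_ISS"], region=(0, 400), count=3),
        Planting(by_name["RBP1_A"], region=(0, 400), count=2),
        Planting(by_name["dsxRE"], region=(1069, 1534), count=5),
    ]
    sequence, truth = plant_motifs(background, plantings, seed=73)
    hits = scan(sequence, DEFAULT_CATALOGUE, regions=layout)
    runs = detect_purine_runs(sequence, min_len=10)
    summary = summarize_regions(hits, runs, layout, "exon5a", "exon5b")

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "bipartite_counts.tsv"
    table = summary.counts.copy()
    table["p_exon5a_vs_exon5b"] = [summary.p_values[m] for m in table.index]
    table.to_csv(out, sep="\t")

    recalled = sum(
        1 for t in truth
        if any(h.motif_name == t["motif"] and h.start == t["start"]
               for h in hits)
    )
    print(summary.counts.to_string())
    print(f"\nplanted instances recalled: {recalled}/{len(truth)}")
    print("exact-test p (exon5a vs exon5b):",
          {k: round(v, 4) for k, v in summary.p_values.items()})
    print("purine-run (PRE candidate) counts per region:",
          summary.purine_runs)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
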