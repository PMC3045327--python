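#!/usr/bin/env python
"""Partitioned pairwise dN/dS: strong versus relaxed purifying selection.

Simulates a 15-taxon codon alignment with an OD1-like partition evolving
at omega = 0.05 and an OD2-like partition at omega = 0.4 (the
relaxed-constraint pattern of the DSX oligomerization domain), then runs
the NG86/Jukes-Cantor pipeline per partition: both partitions classify
purifying, with the OD2-like partition showing the higher mean pairwise
ratio.
"""

from pathlib import Path

import pandas as pd

from aedsx.molevol import partition_summary
from aedsx.simulate import CodonSimConfig, simulate_codon_alignment

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = CodonSimConfig(
        n_taxa=15, subs_per_codon=0.25,
        partitions=[("OD1_like", 150, 0.05), ("OD2_like", 150, 0.4)],
    )
    alignment, truth = simulate_codon_alignment(config, seed=91)
    parts = {name: [tuple(r) for r in rec["ranges"]]
             for name, rec in truth["partitions"].items()}
    summaries = partition_summary(alignment, parts)
    table = pd.DataFrame([
        {
            "partition": s.name,
            "true_omega": truth["partitions"][s.name]["omega"],
            "n_pairs": s.n_pairs,
            "n_excluded": s.n_excluded,
            "mean_dN": round(s.mean_dN, 4),
            "mean_dS": round(s.mean_dS, 4),
            "mean_dN_dS": round(s.mean_ratio, 3),
            "ratio_of_means": round(s.ratio_of_means, 3),
            "classification": s.classification,
        }
        for s in summaries
    ])
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "dnds_partitions.tsv"
    table.to_csv(out, sep="\t", index=False)
    print(table.to_string(index=False))
    od1 = table.set_index("partition").loc["OD1_like", "mean_dN_dS"]
    od2 = table.set_index("partition").loc["OD2_like", "mean_dN_dS"]
    assert od1 < od2, "expected relaxed constraint in the OD2-like partition"
    print(f"\nconstraint ordering recovered: mean dN/dS {od1} (OD1-like) "
          f"< {od2} (OD2-like); both < 1 (purifying)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
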