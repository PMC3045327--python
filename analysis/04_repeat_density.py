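#!/usr/bin/env python
"""Repeat-element depletion in sex-specifically regulated introns.

Simulates repeat annotations at the non-sex-specific background density
(1.13 elements/kb) over four large common introns while keeping the three
sex-specifically regulated introns repeat-free, then recomputes NoRE/kb
and REbp per intron and the group comparison: the planted contrast is
recovered.
"""

from pathlib import Path

from aedsx.genemodel import IntronRecord
from aedsx.repeats import compare_groups, intron_repeat_stats, stats_to_frame
from aedsx.simulate import simulate_repeats

RESULTS = Path(__file__).resolve().parent.parent / "results"

# intron layout: sizes follow the published locus, spaced apart
SIZES = [274879, 43797, 85670, 13860, 208, 10392, 22437]
SEX_SPECIFIC = [False, False, False, True, True, True, False]


def main() -> None:
    introns = []
    pos = 0
    for i, (size, sex) in enumerate(zip(SIZES, SEX_SPECIFIC), start=1):
        introns.append(IntronRecord(f"intron{i}", pos, pos + size,
                                    f"e{i}", f"e{i + 1}", sex))
        pos += size + 1000
    densities = [0.0 if i.sex_specific else 1.13 for i in introns]
    features, truth = simulate_repeats(introns, densities, mean_length=250,
                                       seed=83)
    stats = [intron_repeat_stats(i, features) for i in introns]
    comparison = compare_groups(stats)

    RESULTS.mkdir(exist_ok=True)
    out_stats = RESULTS / "intron_repeat_stats.tsv"
    stats_to_frame(stats).to_csv(out_stats, sep="\t", index=False)
    out_groups = RESULTS / "repeat_group_comparison.tsv"
    comparison.group_means.to_csv(out_groups, sep="\t")

    print(stats_to_frame(stats).to_string(index=False))
    print("\ngroup means:")
    print(comparison.group_means.to_string())
    means = comparison.group_means
    assert means.loc["sex_specific", "nore_per_kb"] \
        < means.loc["non_sex_specific", "nore_per_kb"]
    print("\nplanted contrast recovered: sex-specific introns are "
          "repeat-depleted relative to the common-intron background")
    print(f"wrote {out_stats} and {out_groups}")


if __name__ == "__main__":
    main()
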