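"""Per-intron repeat-element density: NoRE/kb and REbp.

NoRE/kb is the number of annotated repeat elements overlapping an intron
per kb of intron; REbp is the percent of intron nucleotides covered by the
union of (clipped) repeat intervals. Repeat annotations come from a
CENSOR-style TSV; discovery itself is upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genemodel import IntronRecord


class RepeatError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatFeature:
    contig_id: str
    start: int  # 0-based half-open internal
    end: int
    family: str = ""
    repeat_class: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise RepeatError(
                f"repeat {self.family!r}: end {self.end} <= start {self.start}"
            )


@dataclass(frozen=True)
class IntronRepeatStats:
    intron_id: str
    intron_length: int
    n_elements: int
    nore_per_kb: float
    rebp_percent: float
    sex_specific: bool = False


@dataclass
class GroupComparison:
    group_means: pd.DataFrame   # index: group label; columns: nore_per_kb, rebp
    per_intron: pd.DataFrame    # deviation of each intron from the reference mean
    reference_group: str


def load_repeats(path: str | Path) -> list[RepeatFeature]:
    """Read a TSV with columns contig, start, end, family, class.

    Coordinates are 1-based inclusive on disk. Bad rows raise with their
    line number; an empty table warns.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"contig", "start", "end"}
    if not required <= set(df.columns):
        raise RepeatError(
            f"{path}: need columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        warnings.warn(f"empty repeat table {path}")
        return []
    features = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError):
            raise RepeatError(f"{path} line {line_no}: non-numeric coordinates")
        if end < start:
            raise RepeatError(f"{path} line {line_no}: end {end} < start {start}")
        features.append(
            RepeatFeature(
                contig_id=str(row["contig"]),
                start=start - 1,
                end=end,
                family=str(row.get("family", "")),
                repeat_class=str(row.get("class", "")),
            )
        )
    features.sort(key=lambda f: (f.contig_id, f.start))
    return features


def repeats_to_frame(features: Sequence[RepeatFeature]) -> pd.DataFrame:
    """1-based inclusive table for writing back to disk."""
    return pd.DataFrame(
        [
            {
                "contig": f.contig_id, "start": f.start + 1, "end": f.end,
                "family": f.family, "class": f.repeat_class,
            }
            for f in features
        ],
        columns=["contig", "start", "end", "family", "class"],
    )


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_start = cur_end = None
    for s, e in sorted(intervals):
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def intron_repeat_stats(
    intron: IntronRecord,
    features: Iterable[RepeatFeature],
    contig_id: str | None = None,
    sum_coverage: bool = False,
) -> IntronRepeatStats:
    """NoRE/kb and REbp for one intron.

    Any >=1 bp overlap counts an element once; coverage clips features to
    the intron and merges overlaps (``sum_coverage`` reproduces raw
    summation instead, in which case REbp may exceed 100).
    """
    clipped = []
    n = 0
    for f in features:
        if contig_id is not None and f.contig_id != contig_id:
            continue
        s, e = max(f.start, intron.start), min(f.end, intron.end)
        if e > s:
            n += 1
            clipped.append((s, e))
    length = intron.length
    covered = (
        sum(e - s for s, e in clipped) if sum_coverage else _union_length(clipped)
    )
    return IntronRepeatStats(
        intron_id=intron.intron_id,
        intron_length=length,
        n_elements=n,
        nore_per_kb=n / (length / 1000),
        rebp_percent=100 * covered / length,
        sex_specific=intron.sex_specific,
    )


def stats_to_frame(stats: Sequence[IntronRepeatStats]) -> pd.DataFrame:
    # NoRE/kb to 2 decimals, REbp to the nearest percent in the report columns
    return pd.DataFrame(
        [
            {
                "intron_id": s.intron_id,
                "intron_length": s.intron_length,
                "n_elements": s.n_elements,
                "nore_per_kb": round(s.nore_per_kb, 2),
                "rebp_percent": round(s.rebp_percent),
                "sex_specific": s.sex_specific,
            }
            for s in stats
        ]
    )


def compare_groups(
    stats: Sequence[IntronRepeatStats],
    reference_group: str = "non_sex_specific",
) -> GroupComparison:
    """Group means (sex-specific vs not) and per-intron deviations.

    Deviations are relative to the non-sex-specific group means, the
    reference against which depleted sex-specific introns stand out.
    """
    rows = [
        {
            "intron_id": s.intron_id,
            "group": "sex_specific" if s.sex_specific else "non_sex_specific",
            "nore_per_kb": s.nore_per_kb,
            "rebp_percent": s.rebp_percent,
        }
        for s in stats
    ]
    df = pd.DataFrame(rows)
    if df.empty or df["group"].nunique() < 2:
        raise RepeatError("need at least one intron in each group")
    means = df.groupby("group")[["nore_per_kb", "rebp_percent"]].mean()
    ref = means.loc[reference_group]
    per_intron = df.copy()
    per_intron["nore_deviation"] = df["nore_per_kb"] - ref["nore_per_kb"]
    per_intron["rebp_deviation"] = df["rebp_percent"] - ref["rebp_percent"]
    return GroupComparison(
        group_means=means, per_intron=per_intron, reference_group=reference_group
    )
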