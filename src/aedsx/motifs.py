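"""Degenerate cis-element scanning and bipartite region summaries.

The bundled catalogue carries the splicing regulatory elements relevant to
female-specific *doublesex* splicing: the 13-nt Drosophila TRA/TRA-2
binding repeat (dsxRE), the 8-nt Nasonia/Apis repeat (NvdsxRE), the two
RBP1 target types and the TRA-2 intronic splicing silencer. Matching is
IUPAC-degenerate with an optional mismatch budget; purine-rich-element
(PRE) candidates are reported as maximal purine runs since no PRE
consensus is published.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .splice import IUPAC_SETS
from .genemodel import reverse_complement

ELEMENT_CLASSES = {"activator", "silencer", "other"}
PURINES = set("AG")


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    iupac: str
    element_class: str = "other"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.iupac:
            raise MotifError(f"motif {self.name!r}: empty consensus")
        for ch in self.iupac.upper():
            if ch not in IUPAC_SETS:
                raise MotifError(
                    f"motif {self.name!r}: invalid IUPAC code {ch!r}"
                )
        if self.element_class not in ELEMENT_CLASSES:
            raise MotifError(
                f"motif {self.name!r}: unknown class {self.element_class!r}"
            )

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def degeneracy(self) -> int:
        return math.prod(len(IUPAC_SETS[c]) for c in self.iupac.upper())


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    contig_id: str
    start: int  # 0-based, forward coordinates
    end: int
    strand: str
    matched_sequence: str
    mismatches: int
    region_label: str | None = None


@dataclass(frozen=True)
class PurineRun:
    start: int
    end: int
    purine_fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionAnnotation:
    """Labeled non-overlapping intervals (label, start, end), 0-based half-open."""

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.intervals, key=lambda t: t[1])
        for (la, sa, ea), (lb, sb, eb) in zip(ordered, ordered[1:]):
            if sb < ea:
                raise MotifError(f"regions {la!r} and {lb!r} overlap")

    def label_of(self, position: int) -> str | None:
        for label, start, end in self.intervals:
            if start <= position < end:
                return label
        return None

    def length_of(self, label: str) -> int:
        return sum(e - s for l, s, e in self.intervals if l == label)


# TC(T/A)(T/A)CAATCAACA; (T/G)GAAGAT(T/A); DCADCTTTA; ATCYNNA; CAAGR
DEFAULT_CATALOGUE: tuple[MotifDefinition, ...] = (
    MotifDefinition("dsxRE", "TCWWCAATCAACA", "activator",
                    "Drosophila dsx TRA/TRA-2 binding repeat"),
    MotifDefinition("NvdsxRE", "KGAAGATW", "activator",
                    "Nasonia/Apis dsx 8-nt repeat element"),
    MotifDefinition("RBP1_A", "DCADCTTTA", "activator",
                    "RBP1 target, type A"),
    MotifDefinition("RBP1_B", "ATCYNNA", "activator",
                    "RBP1 target, type B"),
    MotifDefinition("TRA2_ISS", "CAAGR", "silencer",
                    "TRA-2 intronic splicing silencer"),
)


def load_catalogue(path: str | Path) -> list[MotifDefinition]:
    """Read a JSON catalogue [{"name","iupac","class","source"}, ...]."""
    with open(path) as fh:
        entries = json.load(fh)
    if not entries:
        warnings.warn(f"empty motif catalogue {path}")
        return []
    motifs = []
    seen = set()
    for entry in entries:
        name = entry["name"]
        if name in seen:
            raise MotifError(f"duplicate motif name {name!r}")
        seen.add(name)
        motifs.append(
            MotifDefinition(
                name=name,
                iupac=entry["iupac"],
                element_class=entry.get("class", "other"),
                source=entry.get("source", ""),
            )
        )
    return motifs


def expand_iupac(motif: MotifDefinition, cap: int = 4096) -> set[str]:
    """Cartesian expansion of a degenerate consensus into literal words."""
    if motif.degeneracy > cap:
        raise MotifError(
            f"motif {motif.name!r} expands to {motif.degeneracy} words "
            f"(cap {cap}); scan by consensus instead"
        )
    sets = [IUPAC_SETS[c] for c in motif.iupac.upper()]
    return {"".join(word) for word in itertools.product(*sets)}


def _mismatch_profile(seq: str, iupac: str) -> np.ndarray:
    """Mismatch count of ``iupac`` at every offset of ``seq`` (vectorized)."""
    n, m = len(seq), len(iupac)
    if m > n:
        return np.empty(0, dtype=np.int32)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n_offsets = n - m + 1
    mism = np.zeros(n_offsets, dtype=np.int32)
    for j, code in enumerate(iupac.upper()):
        table = np.zeros(256, dtype=bool)
        for b in IUPAC_SETS[code]:
            table[ord(b)] = True
        mism += ~table[arr[j:j + n_offsets]]
    return mism


def scan(
    sequence: str,
    motifs: Iterable[MotifDefinition],
    max_mismatch: int = 0,
    strands: str = "forward",
    regions: RegionAnnotation | None = None,
    contig_id: str = "seq",
) -> list[MotifHit]:
    """All offsets where each motif matches within ``max_mismatch``.

    Overlapping hits are all reported. Reverse-strand hits (with
    ``strands='both'``) are given in forward coordinates with strand '-'.
    Region labels are assigned by hit start.
    """
    if strands not in {"forward", "both"}:
        raise MotifError(f"strands must be 'forward' or 'both', got {strands!r}")
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for motif in motifs:
        m = len(motif)
        for strand in ("+", "-") if strands == "both" else ("+",):
            target = seq if strand == "+" else reverse_complement(seq)
            mism = _mismatch_profile(target, motif.iupac)
            for i in np.flatnonzero(mism <= max_mismatch):
                i = int(i)
                start = i if strand == "+" else len(seq) - i - m
                hits.append(
                    MotifHit(
                        motif_name=motif.name,
                        contig_id=contig_id,
                        start=start,
                        end=start + m,
                        strand=strand,
                        matched_sequence=seq[start:start + m],
                        mismatches=int(mism[i]),
                        region_label=(
                            regions.label_of(start) if regions else None
                        ),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.motif_name, h.strand))
    return hits


def detect_purine_runs(
    sequence: str, min_len: int = 10, min_frac: float = 1.0
) -> list[PurineRun]:
    """Maximal purine-rich stretches: PRE candidates.

    With ``min_frac`` 1.0, maximal pure A/G runs of length >= ``min_len``;
    below 1.0, every length-``min_len`` window whose purine fraction meets
    the threshold, with overlapping windows merged.
    """
    if min_len < 2:
        raise MotifError("min_len must be >= 2")
    seq = sequence.upper()
    is_pur = [ch in PURINES for ch in seq]
    runs: list[tuple[int, int]] = []
    if min_frac >= 1.0:
        i = 0
        while i < len(seq):
            if is_pur[i]:
                j = i
                while j < len(seq) and is_pur[j]:
                    j += 1
                if j - i >= min_len:
                    runs.append((i, j))
                i = j
            else:
                i += 1
    else:
        prefix = np.concatenate([[0], np.cumsum(is_pur)])
        current: tuple[int, int] | None = None
        for i in range(len(seq) - min_len + 1):
            frac = (prefix[i + min_len] - prefix[i]) / min_len
            if frac >= min_frac:
                if current and i <= current[1]:
                    current = (current[0], i + min_len)
                else:
                    if current:
                        runs.append(current)
                    current = (i, i + min_len)
        if current:
            runs.append(current)
    return [
        PurineRun(s, e, sum(is_pur[s:e]) / (e - s)) for s, e in runs
    ]


def cluster_hits(hits: Sequence[MotifHit], gap: int = 50) -> list[list[MotifHit]]:
    """Group hits whose starts lie within ``gap`` nt of the previous hit."""
    clusters: list[list[MotifHit]] = []
    for hit in sorted(hits, key=lambda h: h.start):
        if clusters and hit.start - clusters[-1][-1].start <= gap:
            clusters[-1].append(hit)
        else:
            clusters.append([hit])
    return clusters


def expected_chance_hits(
    motif: MotifDefinition,
    region_length: int,
    base_composition: Mapping[str, float] | None = None,
) -> float:
    """Expected hit count of a degenerate motif in random sequence.

    ``(L - m + 1) * prod_i P(position i matches)`` under the supplied base
    composition (uniform by default).
    """
    m = len(motif)
    if region_length < m:
        return 0.0
    if base_composition is None:
        p_match = math.prod(
            len(IUPAC_SETS[c]) / 4 for c in motif.iupac.upper()
        )
    else:
        p_match = math.prod(
            sum(base_composition[b] for b in IUPAC_SETS[c])
            for c in motif.iupac.upper()
        )
    return (region_length - m + 1) * p_match


@dataclass
class BipartiteSummary:
    counts: pd.DataFrame        # rows: motif, columns: region labels
    expected: pd.DataFrame      # chance expectation, same shape
    p_values: dict[str, float]  # per-motif exact-test p, region A vs B
    region_a: str
    region_b: str
    purine_runs: dict[str, int]  # PRE candidates per region


def summarize_regions(
    hits: Sequence[MotifHit],
    runs: Sequence[PurineRun],
    regions: RegionAnnotation,
    region_a: str,
    region_b: str,
    motifs: Iterable[MotifDefinition] = DEFAULT_CATALOGUE,
    base_composition: Mapping[str, float] | None = None,
) -> BipartiteSummary:
    """Per-(motif, region) hit counts with a two-region exact test.

    For each motif, a 2x2 table of hit-bearing vs non-hit-bearing start
    positions in the two designated regions is tested with Fisher's exact
    test (two-sided): the quantitative form of "almost exclusively present
    in one exon".
    """
    labels = sorted({l for l, _, _ in regions.intervals})
    for needed in (region_a, region_b):
        if needed not in labels:
            raise MotifError(f"designated region {needed!r} not annotated")
    motifs = list(motifs)
    counts = pd.DataFrame(0, index=[m.name for m in motifs], columns=labels)
    for hit in hits:
        if hit.region_label in labels and hit.motif_name in counts.index:
            counts.loc[hit.motif_name, hit.region_label] += 1
    expected = pd.DataFrame(
        {
            label: [
                expected_chance_hits(m, regions.length_of(label), base_composition)
                for m in motifs
            ]
            for label in labels
        },
        index=[m.name for m in motifs],
    )
    p_values = {}
    for motif in motifs:
        m = len(motif)
        pos_a = max(regions.length_of(region_a) - m + 1, 0)
        pos_b = max(regions.length_of(region_b) - m + 1, 0)
        hits_a = int(counts.loc[motif.name, region_a])
        hits_b = int(counts.loc[motif.name, region_b])
        table = [[hits_a, pos_a - hits_a], [hits_b, pos_b - hits_b]]
        _, p = _scipy_stats.fisher_exact(table, alternative="two-sided")
        p_values[motif.name] = float(p)
    run_counts = {label: 0 for label in labels}
    for run in runs:
        label = regions.label_of(run.start)
        if label is not None:
            run_counts[label] += 1
    return BipartiteSummary(
        counts=counts, expected=expected, p_values=p_values,
        region_a=region_a, region_b=region_b, purine_runs=run_counts,
    )


def hits_to_bed(hits: Sequence[MotifHit]) -> str:
    """BED6 text: name = motif, score = mismatch count."""
    lines = [
        f"{h.contig_id}\t{h.start}\t{h.end}\t{h.motif_name}\t{h.mismatches}"
        f"\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": h.motif_name, "contig": h.contig_id,
                "start": h.start, "end": h.end, "strand": h.strand,
                "match": h.matched_sequence, "mismatches": h.mismatches,
                "region": h.region_label,
            }
            for h in hits
        ]
    )
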