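"""Pairwise dN/dS by the Nei-Gojobori method with Jukes-Cantor correction.

For each codon, the number of synonymous sites ``s`` is the per-position
fraction of one-step nucleotide changes that preserve the encoded amino
acid; ``n = 3 - s``. Changes that create a stop codon are excluded from
the denominator by default (``exclude_stops=False`` restores the original
3-change denominator, where stop-creating changes count as non-synonymous).
Between two codons differing at k positions, synonymous/non-synonymous
differences are averaged over the k! orderings of single-step changes,
discarding orderings that pass through a stop codon (all orderings are
kept if none survive). Proportions pS = Sd/S and pN = Nd/N are corrected
for multiple hits with the Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3);
the pairwise ratio dN/dS classifies a sequence pair or alignment partition
as evolving under purifying (ratio < 1) or positive (ratio > 1) selection.

Alignments are in-frame nucleotide FASTA; gaps must occupy whole codons.
Partitions are named lists of 1-based inclusive CDS coordinate ranges,
e.g. the DSX OD1 domain versus the common and female-specific parts of OD2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

BASES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))


class MolEvolError(ValueError):
    pass


class SaturationError(MolEvolError):
    """p >= 3/4: the Jukes-Cantor correction is undefined."""


def _require_sense(codon: str) -> None:
    if codon in STOP_CODONS:
        raise MolEvolError(f"stop codon {codon!r}")
    if codon not in GENETIC_CODE:
        raise MolEvolError(f"not a sense codon: {codon!r}")


@lru_cache(maxsize=None)
def count_sites(codon: str, exclude_stops: bool = True) -> tuple[float, float]:
    """Synonymous and non-synonymous site counts (s, n) of one sense codon.

    At each position, s accrues the fraction of possible single-nucleotide
    changes that are synonymous; with ``exclude_stops`` the denominator
    omits changes creating stop codons (positions where every change
    creates a stop contribute 0 synonymous sites).
    """
    codon = codon.upper()
    _require_sense(codon)
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        possible = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant in STOP_CODONS:
                if not exclude_stops:
                    possible += 1  # counted, non-synonymous
                continue
            possible += 1
            if GENETIC_CODE[mutant] == aa:
                syn += 1
        if possible:
            s += syn / possible
    return s, 3.0 - s


@lru_cache(maxsize=None)
def count_differences(
    codon_a: str, codon_b: str, exclude_stop_paths: bool = True
) -> tuple[float, float]:
    """Pathway-averaged synonymous/non-synonymous differences (sd, nd).

    For k differing positions, each of the k! orderings of single-step
    changes is walked and its steps classified by the genetic code;
    orderings whose intermediate codons are stops are discarded (kept only
    if every ordering hits a stop). Always sd + nd = k.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    _require_sense(codon_a)
    _require_sense(codon_b)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        current = codon_a
        sd = nd = 0.0
        for step, pos in enumerate(order):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            intermediate = step < len(order) - 1
            if nxt in STOP_CODONS:
                if exclude_stop_paths and intermediate:
                    return None
                nd += 1.0  # change to/through a stop is non-synonymous
            elif current in STOP_CODONS:
                nd += 1.0
            elif GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd

    results = [walk(order) for order in permutations(diff_positions)]
    valid = [r for r in results if r is not None]
    if not valid:  # every ordering passes through a stop: keep them all
        valid = [
            walk_all for walk_all in (
                _walk_keep_stops(codon_a, codon_b, order)
                for order in permutations(diff_positions)
            )
        ]
    sd = sum(r[0] for r in valid) / len(valid)
    nd = sum(r[1] for r in valid) / len(valid)
    return sd, nd


def _walk_keep_stops(
    codon_a: str, codon_b: str, order: tuple[int, ...]
) -> tuple[float, float]:
    current = codon_a
    sd = nd = 0.0
    for pos in order:
        nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
        if (current in STOP_CODONS or nxt in STOP_CODONS
                or GENETIC_CODE[nxt] != GENETIC_CODE[current]):
            nd += 1.0
        else:
            sd += 1.0
        current = nxt
    return sd, nd


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise MolEvolError(f"negative proportion {p}")
    if p >= 0.75:
        raise SaturationError(f"p = {p} >= 3/4: distance undefined")
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass(frozen=True)
class PairwiseRates:
    id_a: str
    id_b: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    ratio: float | None
    status: str  # ok | dS_zero | saturated | no_data


@dataclass(frozen=True)
class PartitionSummary:
    name: str
    n_pairs: int
    n_excluded: int
    mean_dN: float | None
    mean_dS: float | None
    mean_ratio: float | None       # mean of per-pair ratios (ok pairs)
    ratio_of_means: float | None   # mean dN / mean dS, reported alongside
    classification: str            # purifying | positive | neutral | undetermined


# ---------------------------------------------------------------------------
# Alignment handling


@dataclass
class CodonAlignment:
    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise MolEvolError(f"unequal aligned lengths {sorted(lengths)}")
        length = lengths.pop() if lengths else 0
        if length % 3:
            raise MolEvolError(f"aligned length {length} not divisible by 3")
        for sid, seq in zip(self.ids, self.seqs):
            for i in range(0, length, 3):
                codon = seq[i:i + 3]
                gaps = codon.count("-")
                if gaps not in (0, 3):
                    raise MolEvolError(
                        f"{sid}: partial-codon gap at CDS position {i + 1}"
                    )
                for ch in codon:
                    if ch not in "ACGT-N":
                        raise MolEvolError(f"{sid}: illegal character {ch!r}")

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3 if self.seqs else 0


def load_codon_alignment(path: str | Path) -> CodonAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise MolEvolError(f"need >= 2 aligned sequences in {path}")
    return CodonAlignment(
        ids=[r.id for r in records],
        seqs=[str(r.seq).upper() for r in records],
    )


def load_partitions(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Partition JSON {"name": [[start, end], ...]}, 1-based inclusive."""
    with open(path) as fh:
        raw = json.load(fh)
    parts = {}
    for name, ranges in raw.items():
        parts[name] = [(int(a), int(b)) for a, b in ranges]
    return parts


def _partition_columns(
    length: int, ranges: Sequence[tuple[int, int]] | None
) -> list[int]:
    """0-based codon indices covered by 1-based inclusive CDS ranges."""
    if ranges is None:
        return list(range(length // 3))
    seen: set[int] = set()
    cols: list[int] = []
    for start, end in ranges:
        if start < 1 or end > length:
            raise MolEvolError(f"range ({start}, {end}) outside alignment")
        if (end - start + 1) % 3:
            raise MolEvolError(f"range ({start}, {end}) not codon-sized")
        if (start - 1) % 3:
            raise MolEvolError(f"range ({start}, {end}) off codon frame")
        for codon_idx in range((start - 1) // 3, end // 3):
            if codon_idx in seen:
                raise MolEvolError("overlapping partition ranges")
            seen.add(codon_idx)
            cols.append(codon_idx)
    return cols


def pairwise_ng86(
    seq_a: str,
    seq_b: str,
    id_a: str = "A",
    id_b: str = "B",
    codon_indices: Sequence[int] | None = None,
    exclude_stops: bool = True,
) -> PairwiseRates:
    """NG86 counts and JC-corrected dS/dN for one aligned sequence pair.

    Codons containing a gap, N, or a stop in either sequence are dropped
    pairwise. S and N are averaged over the two sequences' site counts;
    dN/dS is undefined when dS = 0 (status ``dS_zero``) and when either
    proportion saturates (status ``saturated``).
    """
    if len(seq_a) != len(seq_b):
        raise MolEvolError("aligned sequences differ in length")
    indices = (
        codon_indices if codon_indices is not None
        else range(len(seq_a) // 3)
    )
    S_a = S_b = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    for idx in indices:
        ca = seq_a[3 * idx:3 * idx + 3].upper()
        cb = seq_b[3 * idx:3 * idx + 3].upper()
        if ("-" in ca or "-" in cb or "N" in ca or "N" in cb
                or ca in STOP_CODONS or cb in STOP_CODONS):
            continue
        n_codons += 1
        sa, _ = count_sites(ca, exclude_stops)
        sb, _ = count_sites(cb, exclude_stops)
        S_a += sa
        S_b += sb
        sd, nd = count_differences(ca, cb, exclude_stops)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise MolEvolError(f"no comparable codons between {id_a} and {id_b}")
    S = (S_a + S_b) / 2
    N = 3 * n_codons - S
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    status = "ok"
    dS = dN = ratio = None
    try:
        dS = jc_correct(pS)
        dN = jc_correct(pN)
    except SaturationError:
        status = "saturated"
    if status == "ok":
        if dS == 0:
            status = "dS_zero"
        else:
            ratio = dN / dS
    return PairwiseRates(
        id_a=id_a, id_b=id_b, n_codons=n_codons,
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        dS=dS, dN=dN, ratio=ratio, status=status,
    )


def all_pairs(
    alignment: CodonAlignment,
    codon_indices: Sequence[int] | None = None,
    exclude_stops: bool = True,
) -> list[PairwiseRates]:
    out = []
    for (i, j) in combinations(range(len(alignment.ids)), 2):
        out.append(
            pairwise_ng86(
                alignment.seqs[i], alignment.seqs[j],
                alignment.ids[i], alignment.ids[j],
                codon_indices=codon_indices, exclude_stops=exclude_stops,
            )
        )
    return out


def partition_summary(
    alignment: CodonAlignment,
    partitions: Mapping[str, Sequence[tuple[int, int]] | None],
    exclude_stops: bool = True,
) -> list[PartitionSummary]:
    """Mean pairwise dN, dS and dN/dS per named coordinate partition.

    Means are over pairs with status ok; excluded pairs (dS_zero or
    saturated) are counted. The mean of per-pair ratios is the headline
    number; the ratio of mean rates is reported alongside.
    """
    if len(alignment.ids) < 2:
        raise MolEvolError("need >= 2 sequences")
    length = len(alignment.seqs[0])
    summaries = []
    for name, ranges in partitions.items():
        cols = _partition_columns(length, ranges)
        if not cols:
            raise MolEvolError(f"partition {name!r} covers no codons")
        pairs = all_pairs(alignment, codon_indices=cols,
                          exclude_stops=exclude_stops)
        ok = [p for p in pairs if p.status == "ok"]
        excluded = len(pairs) - len(ok)
        if not ok:
            summaries.append(
                PartitionSummary(name, 0, excluded, None, None, None, None,
                                 "undetermined")
            )
            continue
        mean_dn = sum(p.dN for p in ok) / len(ok)
        mean_ds = sum(p.dS for p in ok) / len(ok)
        mean_ratio = sum(p.ratio for p in ok) / len(ok)
        rom = mean_dn / mean_ds if mean_ds else None
        if mean_ratio < 1:
            classification = "purifying"
        elif mean_ratio > 1:
            classification = "positive"
        else:
            classification = "neutral"
        summaries.append(
            PartitionSummary(
                name=name, n_pairs=len(ok), n_excluded=excluded,
                mean_dN=mean_dn, mean_dS=mean_ds, mean_ratio=mean_ratio,
                ratio_of_means=rom, classification=classification,
            )
        )
    return summaries


def pairs_to_frame(pairs: Sequence[PairwiseRates],
                   partition: str = "all") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "idA": p.id_a, "idB": p.id_b, "partition": partition,
                "n_codons": p.n_codons, "S": p.S, "N": p.N,
                "Sd": p.Sd, "Nd": p.Nd, "pS": p.pS, "pN": p.pN,
                "dS": p.dS, "dN": p.dN, "ratio": p.ratio, "status": p.status,
            }
            for p in pairs
        ]
    )


def aligned_identity(identical: int, aligned: int) -> tuple[float, int]:
    """Percent identity over aligned positions, with the rounded report value.

    166 identical of 282 aligned -> (58.87..., 59).
    """
    if aligned <= 0:
        raise MolEvolError("aligned count must be positive")
    if not 0 <= identical <= aligned:
        raise MolEvolError("identical count outside [0, aligned]")
    percent = 100.0 * identical / aligned
    return percent, math.floor(percent + 0.5)
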