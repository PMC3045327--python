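"""Microsynteny quality between two genomic regions.

Synteny quality is the percentage of conserved (homologous) genes among
the genes of two compared regions. The published convention divides the
number of conserved homologue pairs by a printed total gene count
(10 of 16 -> 62%); the literal two-region formula (2|pairs| / (|A|+|B|))
is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class RegionGene:
    gene_id: str
    start: int
    end: int
    strand: str


@dataclass
class RegionGeneSet:
    label: str
    genes: list[RegionGene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise SyntenyError(f"region {self.label!r}: duplicate gene ids")

    def position_of(self, gene_id: str) -> int:
        order = sorted(self.genes, key=lambda g: g.start)
        for i, g in enumerate(order):
            if g.gene_id == gene_id:
                return i
        raise SyntenyError(f"gene {gene_id!r} not in region {self.label!r}")


@dataclass(frozen=True)
class SyntenyResult:
    n_conserved: int
    n_total: int
    quality_percent: float
    reported_percent: int
    convention: str


def _round_percent(x: float) -> int:
    # round-half-even: 62.5 reports as the conventional 62
    return int(round(x))


def _check_pairs(
    set_a: RegionGeneSet, set_b: RegionGeneSet, pairs: Sequence[tuple[str, str]]
) -> None:
    ids_a = {g.gene_id for g in set_a.genes}
    ids_b = {g.gene_id for g in set_b.genes}
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for ga, gb in pairs:
        if ga not in ids_a:
            raise SyntenyError(f"pair references unknown gene {ga!r} in A")
        if gb not in ids_b:
            raise SyntenyError(f"pair references unknown gene {gb!r} in B")
        if ga in seen_a or gb in seen_b:
            raise SyntenyError(f"gene duplicated across pairs: ({ga!r}, {gb!r})")
        seen_a.add(ga)
        seen_b.add(gb)


def synteny_quality(
    set_a: RegionGeneSet,
    set_b: RegionGeneSet,
    pairs: Sequence[tuple[str, str]],
    convention: str = "pairs_over_printed_total",
    n_total: int | None = None,
) -> SyntenyResult:
    """Percent of conserved genes between two regions.

    ``pairs_over_printed_total`` divides |pairs| by a supplied total
    (default |A| + |B|); ``pairs_over_combined_total`` divides 2|pairs| by
    |A| + |B|. Reported value is rounded half-up to an integer percent.
    """
    _check_pairs(set_a, set_b, pairs)
    combined = len(set_a.genes) + len(set_b.genes)
    if convention == "pairs_over_printed_total":
        total = n_total if n_total is not None else combined
        quality = 100.0 * len(pairs) / total
    elif convention == "pairs_over_combined_total":
        total = combined
        quality = 100.0 * 2 * len(pairs) / total
    else:
        raise SyntenyError(f"unknown convention {convention!r}")
    return SyntenyResult(
        n_conserved=len(pairs),
        n_total=total,
        quality_percent=quality,
        reported_percent=_round_percent(quality),
        convention=convention,
    )


@dataclass(frozen=True)
class OrderConservation:
    n_inversions: int
    discordant_pairs: tuple[tuple[str, str], ...]  # (geneA_i, geneA_j)
    strand_flips: tuple[str, ...]  # geneA ids of pairs on opposite strands


def order_conservation(
    set_a: RegionGeneSet,
    set_b: RegionGeneSet,
    pairs: Sequence[tuple[str, str]],
) -> OrderConservation:
    """Gene-order inversions and strand flips across two paired regions.

    Pairs are sorted by position in A; every pair of pairs whose order in B
    disagrees counts one inversion (discordant-pair / Kendall count).
    """
    _check_pairs(set_a, set_b, pairs)
    strand_a = {g.gene_id: g.strand for g in set_a.genes}
    strand_b = {g.gene_id: g.strand for g in set_b.genes}
    ordered = sorted(pairs, key=lambda p: set_a.position_of(p[0]))
    b_positions = [set_b.position_of(gb) for _, gb in ordered]
    discordant = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if b_positions[i] > b_positions[j]:
                discordant.append((ordered[i][0], ordered[j][0]))
    flips = tuple(
        ga for ga, gb in ordered if strand_a[ga] != strand_b[gb]
    )
    return OrderConservation(
        n_inversions=len(discordant),
        discordant_pairs=tuple(discordant),
        strand_flips=flips,
    )


def span_ratio_fold(span_a_bp: float, span_b_bp: float) -> float:
    """Fold difference between two genomic spans, one decimal place."""
    if span_b_bp <= 0:
        raise SyntenyError("reference span must be positive")
    return round(span_a_bp / span_b_bp, 1)
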