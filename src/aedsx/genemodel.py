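"""Gene models, intron derivation and exon-intron junction windows.

A :class:`GeneModel` is an ordered list of classified exons on one contig.
Introns are the gaps between transcription-adjacent exons; each intron
carries a donor window (last 6 exonic nt + first 16 intronic nt) and an
acceptor window (last 16 intronic nt + first 6 nt of the following exon),
the format in which exon-intron junctions of the mosquito *doublesex* locus
are conventionally tabulated.

Coordinates are 0-based half-open internally and 1-based inclusive at the
GFF3 boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

VALID_BASES = set("ACGTN")
EXON_CLASSES = {"common", "female_specific", "male_specific", "utr"}
SEX_CLASSES = {"female_specific", "male_specific"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GeneModelError(ValueError):
    """Raised for malformed genomes, gene models or class maps."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One contig, uppercase, alphabet {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GeneModelError(f"contig {self.contig_id!r}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in VALID_BASES:
                raise GeneModelError(
                    f"contig {self.contig_id!r}: illegal character "
                    f"{ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExonRecord:
    exon_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    class_label: str = "common"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise GeneModelError(
                f"exon {self.exon_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise GeneModelError(f"exon {self.exon_id!r}: bad strand {self.strand!r}")
        if self.class_label not in EXON_CLASSES:
            raise GeneModelError(
                f"exon {self.exon_id!r}: unknown class {self.class_label!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Exons of one gene in transcription order on a single contig/strand."""

    gene_id: str
    contig_id: str
    strand: str
    exons: list[ExonRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(e.strand != self.strand for e in self.exons):
            raise GeneModelError(f"gene {self.gene_id!r}: mixed strands")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start < a.end:
                raise GeneModelError(
                    f"gene {self.gene_id!r}: exons {a.exon_id!r} and "
                    f"{b.exon_id!r} overlap"
                )
        # transcription order: genomic order on '+', reversed on '-'
        self.exons = genomic if self.strand == "+" else genomic[::-1]

    @property
    def span(self) -> int:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        return max(ends) - min(starts)


@dataclass(frozen=True)
class IntronRecord:
    intron_id: str
    start: int  # genomic, 0-based half-open
    end: int
    preceding_exon_id: str  # transcriptionally upstream
    following_exon_id: str
    sex_specific: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class JunctionContext:
    """Windows around one intron, in transcription orientation.

    ``donor_exonic``/``donor_intronic`` sit at the intron's 5' end,
    ``acceptor_intronic``/``acceptor_exonic`` at its 3' end; the acceptor
    window always ends at the terminal dinucleotide. Windows shorter than
    the nominal 6/16/16/6 (short flanking feature or contig edge) are kept
    and flagged ``truncated``.
    """

    intron_id: str
    donor_exonic: str
    donor_intronic: str
    acceptor_intronic: str
    acceptor_exonic: str
    truncated: bool


@dataclass(frozen=True)
class GeneSummary:
    gene_id: str
    span_bp: int
    n_exons: int
    n_introns: int
    intron_min_bp: int
    intron_max_bp: int
    intron_mean_bp: float
    intron_mean_kb: int  # rounded for reporting


# ---------------------------------------------------------------------------
# I/O


def load_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (multi-record) FASTA into uppercase :class:`GenomeSequence`.

    Duplicate contig ids and characters outside {A,C,G,T,N} are errors.
    """
    genome: dict[str, GenomeSequence] = {}
    with open(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in genome:
                raise GeneModelError(
                    f"duplicate contig id {record.id!r} in {path}"
                )
            genome[record.id] = GenomeSequence(record.id,
                                               str(record.seq).upper())
    if not genome:
        raise GeneModelError(f"no FASTA records in {path}")
    return genome


def load_class_map(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        mapping = json.load(fh)
    for key, label in mapping.items():
        if label not in EXON_CLASSES:
            raise GeneModelError(f"class map {key!r}: unknown class {label!r}")
    return mapping


def load_gene_model(
    gff_path: str | Path,
    class_map: Mapping[str, str] | str | Path | None = None,
    genome: Mapping[str, GenomeSequence] | None = None,
    gene_id: str | None = None,
) -> GeneModel:
    """Read one gene's exons from GFF3, with classes from a sidecar map.

    Exon classes come from, in priority order: the ``class_map`` (keyed by
    exon ID), an ``exon_class`` GFF attribute, else ``common``. When a
    ``genome`` is given, coordinates are checked against contig length.
    """
    import gffutils

    if class_map is not None and not isinstance(class_map, Mapping):
        class_map = load_class_map(class_map)
    class_map = dict(class_map or {})

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    exons_by_gene: dict[str, list] = {}
    for feat in db.features_of_type("exon"):
        parent = (feat.attributes.get("Parent") or feat.attributes.get("gene_id")
                  or ["unnamed_gene"])[0]
        exons_by_gene.setdefault(parent, []).append(feat)
    if not exons_by_gene:
        raise GeneModelError(f"no exon features in {gff_path}")
    if gene_id is None:
        if len(exons_by_gene) > 1:
            raise GeneModelError(
                f"{gff_path} contains {len(exons_by_gene)} genes; pass gene_id"
            )
        gene_id = next(iter(exons_by_gene))
    if gene_id not in exons_by_gene:
        raise GeneModelError(f"gene {gene_id!r} not found in {gff_path}")

    feats = exons_by_gene[gene_id]
    contigs = {f.seqid for f in feats}
    if len(contigs) > 1:
        raise GeneModelError(f"gene {gene_id!r}: exons on multiple contigs {contigs}")
    contig_id = contigs.pop()
    strands = {f.strand for f in feats}
    if len(strands) > 1:
        raise GeneModelError(f"gene {gene_id!r}: mixed strands")
    strand = strands.pop()

    exons = []
    for f in feats:
        eid = (f.attributes.get("ID") or [f"{gene_id}:exon:{f.start}"])[0]
        label = class_map.get(eid)
        if label is None:
            label = (f.attributes.get("exon_class") or ["common"])[0]
        if genome is not None:
            if contig_id not in genome:
                raise GeneModelError(f"contig {contig_id!r} absent from genome")
            if f.end > len(genome[contig_id]):
                raise GeneModelError(
                    f"exon {eid!r} end {f.end} exceeds contig length "
                    f"{len(genome[contig_id])}"
                )
        exons.append(ExonRecord(eid, f.start - 1, f.end, strand, label))
    return GeneModel(gene_id, contig_id, strand, exons)


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    """Write exon features as GFF3 (1-based inclusive); round-trips exactly."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for exon in sorted(model.exons, key=lambda e: e.start):
            attrs = (
                f"ID={exon.exon_id};Parent={model.gene_id};"
                f"exon_class={exon.class_label}"
            )
            fh.write(
                f"{model.contig_id}\taedsx\texon\t{exon.start + 1}\t{exon.end}"
                f"\t.\t{model.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Derivations


def default_sex_predicate(upstream: ExonRecord, downstream: ExonRecord) -> bool:
    """An intron is sex-specific when either flanking exon is."""
    return (upstream.class_label in SEX_CLASSES
            or downstream.class_label in SEX_CLASSES)


def derive_introns(
    model: GeneModel,
    sex_predicate: Callable[[ExonRecord, ExonRecord], bool] = default_sex_predicate,
) -> list[IntronRecord]:
    """One intron per transcription-adjacent exon pair; zero gaps are errors."""
    if len(model.exons) < 2:
        raise GeneModelError(
            f"gene {model.gene_id!r}: need >= 2 exons to derive introns"
        )
    introns = []
    for i, (up, down) in enumerate(zip(model.exons, model.exons[1:]), start=1):
        start = min(up.end, down.end)
        end = max(up.start, down.start)
        if end <= start:
            raise GeneModelError(
                f"gene {model.gene_id!r}: zero-length intron between "
                f"{up.exon_id!r} and {down.exon_id!r}"
            )
        introns.append(
            IntronRecord(
                intron_id=f"{model.gene_id}:intron:{i}",
                start=start,
                end=end,
                preceding_exon_id=up.exon_id,
                following_exon_id=down.exon_id,
                sex_specific=sex_predicate(up, down),
            )
        )
    return introns


def _slice(seq: str, start: int, end: int) -> str:
    return seq[max(start, 0):max(end, 0)]


def extract_junctions(
    model: GeneModel, genome: GenomeSequence
) -> list[JunctionContext]:
    """Donor/acceptor windows for every intron, in transcription orientation.

    On the '-' strand windows are taken from the reverse complement so that
    the donor window always starts at the intron's transcriptional 5' end.
    """
    if genome.contig_id != model.contig_id:
        raise GeneModelError(
            f"gene {model.gene_id!r} is on {model.contig_id!r}, "
            f"not {genome.contig_id!r}"
        )
    seq = genome.sequence
    out = []
    exon_by_id = {e.exon_id: e for e in model.exons}
    for intron in derive_introns(model):
        up = exon_by_id[intron.preceding_exon_id]
        down = exon_by_id[intron.following_exon_id]
        if model.strand == "+":
            donor_ex = _slice(seq, up.end - 6, up.end)
            donor_in = _slice(seq, intron.start, intron.start + 16)
            accept_in = _slice(seq, intron.end - 16, intron.end)
            accept_ex = _slice(seq, down.start, down.start + 6)
        else:
            donor_ex = reverse_complement(_slice(seq, up.start, up.start + 6))
            donor_in = reverse_complement(_slice(seq, intron.end - 16, intron.end))
            accept_in = reverse_complement(
                _slice(seq, intron.start, intron.start + 16)
            )
            accept_ex = reverse_complement(_slice(seq, down.end - 6, down.end))
        truncated = (
            len(donor_ex) < 6 or len(donor_in) < 16
            or len(accept_in) < 16 or len(accept_ex) < 6
        )
        out.append(
            JunctionContext(
                intron.intron_id, donor_ex, donor_in, accept_in, accept_ex,
                truncated,
            )
        )
    return out


def summarize_gene(model: GeneModel) -> GeneSummary:
    introns = derive_introns(model)
    lengths = [i.length for i in introns]
    mean_bp = sum(lengths) / len(lengths)
    return GeneSummary(
        gene_id=model.gene_id,
        span_bp=sum(e.length for e in model.exons) + sum(lengths),
        n_exons=len(model.exons),
        n_introns=len(introns),
        intron_min_bp=min(lengths),
        intron_max_bp=max(lengths),
        intron_mean_bp=mean_bp,
        intron_mean_kb=round(mean_bp / 1000),
    )


def junction_report(
    model: GeneModel, genome: GenomeSequence
) -> pd.DataFrame:
    """Per-intron junction table (exon id, sizes, donor and acceptor windows)."""
    introns = derive_introns(model)
    junctions = extract_junctions(model, genome)
    exon_by_id = {e.exon_id: e for e in model.exons}
    rows = []
    for intron, ctx in zip(introns, junctions):
        up = exon_by_id[intron.preceding_exon_id]
        rows.append(
            {
                "exon_id": up.exon_id,
                "exon_size": up.length,
                "donor_exonic": ctx.donor_exonic,
                "donor_intronic": ctx.donor_intronic,
                "intron_size": intron.length,
                "acceptor_intronic": ctx.acceptor_intronic,
                "acceptor_exonic": ctx.acceptor_exonic,
                "sex_specific": intron.sex_specific,
                "truncated": ctx.truncated,
            }
        )
    return pd.DataFrame(rows)
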