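"""Synthetic fixtures with known ground truth for every pipeline stage.

The generator emulates the statistical structure the locus analyses
assume: a multi-exon gene with sex-specific exons whose acceptor windows
have controllable pyrimidine content and whose donors match the GTRAGT
consensus with controllable fidelity; planted degenerate motifs at
recorded coordinates; Poisson-process repeat annotations at a target
NoRE/kb; and star-tree codon alignments evolved at a target dN/dS.
Every generator is a pure function of its configuration and a mandatory
seed: reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genemodel import ExonRecord, GeneModel, GenomeSequence, write_gene_model
from .molevol import (BASES, GENETIC_CODE, SENSE_CODONS, STOP_CODONS,
                      CodonAlignment)
from .motifs import MotifDefinition, expand_iupac
from .repeats import RepeatFeature, repeats_to_frame
from .splice import DONOR_CONSENSUS, IUPAC_SETS

PURINES = "AG"
PYRIMIDINES = "CT"
MIN_INTRON = 32  # must host a 16-nt donor and a 16-nt acceptor window


class SimulationError(ValueError):
    pass


def _rng(seed: int) -> np.random.Generator:
    if seed is None:
        raise SimulationError("a seed is required for every stochastic call")
    return np.random.default_rng(seed)


def _random_bases(rng: np.random.Generator, n: int,
                  alphabet: str = BASES) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n else ""


# ---------------------------------------------------------------------------
# Locus simulation


@dataclass
class LocusConfig:
    """Layout and window composition of a simulated gene.

    ``acceptor_p`` is the per-position Bernoulli probability that each of
    the 12 Y-consensus acceptor positions is a pyrimidine; ``donor_fidelity``
    is the number of leading GTRAGT positions forced to match (the rest are
    forced mismatches, so the donor score is exactly the fidelity).
    Scalars broadcast over introns.
    """

    exon_sizes: Sequence[int]
    exon_classes: Sequence[str]
    intron_sizes: Sequence[int]
    acceptor_p: float | Sequence[float] = 0.668
    donor_fidelity: int | Sequence[int] = 6
    acceptor_terminus: str | Sequence[str] = "AG"
    gene_id: str = "simgene"
    contig_id: str = "simcontig"
    flank: int = 20

    def __post_init__(self) -> None:
        if len(self.exon_sizes) != len(self.exon_classes):
            raise SimulationError("exon_sizes and exon_classes differ in length")
        if len(self.intron_sizes) != len(self.exon_sizes) - 1:
            raise SimulationError("need exactly one intron per adjacent exon pair")
        for size in self.intron_sizes:
            if size < MIN_INTRON:
                raise SimulationError(
                    f"intron of {size} bp cannot host both junction windows "
                    f"(minimum {MIN_INTRON})"
                )
        n = len(self.intron_sizes)
        if np.isscalar(self.acceptor_p):
            self.acceptor_p = [float(self.acceptor_p)] * n
        if np.isscalar(self.donor_fidelity):
            self.donor_fidelity = [int(self.donor_fidelity)] * n
        if isinstance(self.acceptor_terminus, str):
            self.acceptor_terminus = [self.acceptor_terminus] * n
        for p in self.acceptor_p:
            if not 0 <= p <= 1:
                raise SimulationError(f"acceptor_p {p} outside [0, 1]")


@dataclass
class LocusFixture:
    genome: GenomeSequence
    model: GeneModel
    truth: dict


def _donor_window(rng: np.random.Generator, fidelity: int) -> str:
    out = []
    for i, code in enumerate(DONOR_CONSENSUS):
        allowed = IUPAC_SETS[code]
        if i < fidelity:
            out.append(str(rng.choice(list(allowed))))
        else:
            forbidden = [b for b in BASES if b not in allowed]
            out.append(str(rng.choice(forbidden)))
    return "".join(out) + _random_bases(rng, 10)


def _acceptor_window(rng: np.random.Generator, p: float,
                     terminus: str) -> tuple[str, int]:
    positions = []
    y_count = 0
    for _ in range(12):
        if rng.random() < p:
            positions.append(str(rng.choice(list(PYRIMIDINES))))
            y_count += 1
        else:
            positions.append(str(rng.choice(list(PURINES))))
    window = "".join(positions) + _random_bases(rng, 2) + terminus
    return window, y_count


def simulate_locus(config: LocusConfig, seed: int) -> LocusFixture:
    """Generate a genome contig plus classified gene model.

    The truth record carries each intron's generating pyrimidine
    probability, realized Y count, donor fidelity and window coordinates.
    """
    rng = _rng(seed)
    pieces = [_random_bases(rng, config.flank)]
    pos = config.flank
    exons: list[ExonRecord] = []
    intron_truth = []
    n_exons = len(config.exon_sizes)
    for i, (size, label) in enumerate(zip(config.exon_sizes,
                                          config.exon_classes)):
        exons.append(
            ExonRecord(f"exon{i + 1}", pos, pos + size, "+", label)
        )
        pieces.append(_random_bases(rng, size))
        pos += size
        if i < n_exons - 1:
            intron_len = config.intron_sizes[i]
            donor = _donor_window(rng, config.donor_fidelity[i])
            acceptor, y_count = _acceptor_window(
                rng, config.acceptor_p[i], config.acceptor_terminus[i]
            )
            middle = _random_bases(rng, intron_len - len(donor) - len(acceptor))
            pieces.append(donor + middle + acceptor)
            intron_truth.append(
                {
                    "intron_index": i + 1,
                    "start": pos,
                    "end": pos + intron_len,
                    "acceptor_p": config.acceptor_p[i],
                    "true_y_count": y_count,
                    "donor_fidelity": config.donor_fidelity[i],
                    "acceptor_terminus": config.acceptor_terminus[i],
                }
            )
            pos += intron_len
    pieces.append(_random_bases(rng, config.flank))
    genome = GenomeSequence(config.contig_id, "".join(pieces))
    model = GeneModel(config.gene_id, config.contig_id, "+", exons)
    return LocusFixture(genome=genome, model=model,
                        truth={"introns": intron_truth, "seed": seed})


def write_locus(fixture: LocusFixture, outdir: str | Path,
                wrap: int = 70) -> dict[str, str]:
    """Write genome FASTA, gene GFF3, class-map JSON and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    seq = fixture.genome.sequence
    with open(fasta, "w") as fh:
        fh.write(f">{fixture.genome.contig_id}\n")
        for i in range(0, len(seq), wrap):
            fh.write(seq[i:i + wrap] + "\n")
    gff = outdir / "gene.gff3"
    write_gene_model(fixture.model, gff)
    class_map = outdir / "class_map.json"
    with open(class_map, "w") as fh:
        json.dump(
            {e.exon_id: e.class_label for e in fixture.model.exons},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    truth = outdir / "truth.json"
    with open(truth, "w") as fh:
        json.dump(fixture.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"genome": str(fasta), "gene_model": str(gff),
            "class_map": str(class_map), "truth": str(truth)}


# ---------------------------------------------------------------------------
# Motif planting


@dataclass(frozen=True)
class Planting:
    motif: MotifDefinition
    region: tuple[int, int] | None = None  # 0-based half-open
    count: int = 1
    offsets: tuple[int, ...] | None = None  # explicit coordinates


def plant_motifs(
    sequence: str, plantings: Sequence[Planting], seed: int
) -> tuple[str, list[dict]]:
    """Write literal motif instances into a background sequence.

    Each instance is drawn uniformly from the motif's IUPAC expansion.
    Offsets are either explicit or drawn uniformly within the planting's
    region without overlapping previously placed instances; collisions and
    out-of-bounds plantings are errors. Returns the edited sequence and a
    truth list of (motif, start, word).
    """
    rng = _rng(seed)
    seq = list(sequence.upper())
    occupied: list[tuple[int, int]] = []
    truth = []

    def collides(start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in occupied)

    for planting in plantings:
        m = len(planting.motif)
        words = sorted(expand_iupac(planting.motif))
        explicit = planting.offsets is not None
        if explicit:
            chosen = list(planting.offsets)
        else:
            lo, hi = planting.region or (0, len(seq))
            if hi - lo < m:
                raise SimulationError(
                    f"region ({lo}, {hi}) too short for "
                    f"{m}-nt motif {planting.motif.name!r}"
                )
            chosen = []
            for _ in range(planting.count):
                placed = False
                for _attempt in range(1000):
                    start = int(rng.integers(lo, hi - m + 1))
                    if not collides(start, start + m):
                        chosen.append(start)
                        occupied.append((start, start + m))
                        placed = True
                        break
                if not placed:
                    raise SimulationError(
                        f"could not place motif {planting.motif.name!r} "
                        f"without collision"
                    )
        for start in chosen:
            end = start + m
            if start < 0 or end > len(seq):
                raise SimulationError(
                    f"planting of {planting.motif.name!r} at {start} "
                    f"outside sequence"
                )
            if explicit:
                if collides(start, end):
                    raise SimulationError(
                        f"planting collision for {planting.motif.name!r} "
                        f"at {start}"
                    )
                occupied.append((start, end))
            word = words[int(rng.integers(len(words)))]
            seq[start:end] = word
            truth.append(
                {"motif": planting.motif.name, "start": start, "word": word}
            )
    truth.sort(key=lambda t: t["start"])
    return "".join(seq), truth


# ---------------------------------------------------------------------------
# Repeat annotations


def simulate_repeats(
    introns: Sequence,  # IntronRecord-like with .start/.end/.intron_id
    density_per_kb: float | Sequence[float],
    mean_length: float,
    seed: int,
    contig_id: str = "simcontig",
) -> tuple[list[RepeatFeature], dict]:
    """Poisson-process repeat annotations over intron intervals.

    Element counts per intron are Poisson with mean density * length/1000;
    starts are uniform within the intron, lengths geometric with the given
    mean, clipped at the intron end.
    """
    rng = _rng(seed)
    if np.isscalar(density_per_kb):
        density_per_kb = [float(density_per_kb)] * len(introns)
    features = []
    truth = {"per_intron": [], "seed": seed}
    for intron, density in zip(introns, density_per_kb):
        length = intron.end - intron.start
        n = int(rng.poisson(density * length / 1000))
        for k in range(n):
            start = int(rng.integers(intron.start, intron.end))
            rep_len = int(rng.geometric(1 / mean_length))  # mean = mean_length
            end = min(start + rep_len, intron.end)
            features.append(
                RepeatFeature(contig_id, start, end,
                              family=f"SIM-{intron.intron_id}-{k}",
                              repeat_class="Simulated")
            )
        truth["per_intron"].append(
            {"intron_id": intron.intron_id, "density_per_kb": density,
             "n_elements": n}
        )
    features.sort(key=lambda f: (f.contig_id, f.start))
    return features, truth


def write_repeats(features: Sequence[RepeatFeature],
                  path: str | Path) -> None:
    repeats_to_frame(features).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Codon alignment simulation


def _random_ancestor(rng: np.random.Generator, n_codons: int) -> list[str]:
    codons = list(SENSE_CODONS)
    return [codons[int(i)] for i in rng.integers(0, len(codons), n_codons)]


def _evolve(
    rng: np.random.Generator,
    codons: list[str],
    subs_per_codon: float,
    omega: float,
) -> list[str]:
    """One star-tree branch: Poisson-many proposed single-base events.

    A proposal picks a uniform codon, position and alternative base.
    Stop-creating proposals are rejected outright; synonymous proposals are
    always accepted; non-synonymous ones are accepted with probability
    omega (omega is an acceptance probability, a simulation device, not a
    mechanistic mutation model).
    """
    out = list(codons)
    n_events = int(rng.poisson(subs_per_codon * len(out)))
    for _ in range(n_events):
        idx = int(rng.integers(len(out)))
        pos = int(rng.integers(3))
        current = out[idx]
        alternatives = [b for b in BASES if b != current[pos]]
        base = alternatives[int(rng.integers(3))]
        mutant = current[:pos] + base + current[pos + 1:]
        if mutant in STOP_CODONS:
            continue
        if GENETIC_CODE[mutant] == GENETIC_CODE[current]:
            out[idx] = mutant
        elif rng.random() < omega:
            out[idx] = mutant
    return out


@dataclass
class CodonSimConfig:
    n_taxa: int = 8
    n_codons: int = 300
    subs_per_codon: float = 0.25  # proposed events per codon per branch
    omega: float = 0.4
    partitions: Sequence[tuple[str, int, float]] | None = None
    # partitions: (name, n_codons, omega) segments, concatenated in order

    def __post_init__(self) -> None:
        omegas = ([self.omega] if self.partitions is None
                  else [w for _, _, w in self.partitions])
        for w in omegas:
            if not 0 <= w <= 5:
                raise SimulationError(f"omega {w} outside [0, 5]")


def simulate_codon_alignment(
    config: CodonSimConfig, seed: int
) -> tuple[CodonAlignment, dict]:
    """Star-tree codon alignment at one or more target omega values.

    With ``partitions``, each named segment evolves at its own omega and
    the truth record carries 1-based inclusive CDS coordinates per segment.
    """
    rng = _rng(seed)
    segments = (
        config.partitions
        if config.partitions is not None
        else [("all", config.n_codons, config.omega)]
    )
    seg_ancestors = {
        name: _random_ancestor(rng, n) for name, n, _ in segments
    }
    ids = [f"taxon{i + 1}" for i in range(config.n_taxa)]
    seqs = []
    for _ in ids:
        parts = []
        for name, n, omega in segments:
            evolved = _evolve(rng, seg_ancestors[name],
                              config.subs_per_codon, omega)
            parts.append("".join(evolved))
        seqs.append("".join(parts))
    coords = {}
    offset = 0
    for name, n, omega in segments:
        coords[name] = {"ranges": [[offset * 3 + 1, (offset + n) * 3]],
                        "omega": omega}
        offset += n
    truth = {
        "seed": seed,
        "subs_per_codon": config.subs_per_codon,
        "partitions": coords,
        "ancestor": {k: "".join(v) for k, v in seg_ancestors.items()},
    }
    return CodonAlignment(ids=ids, seqs=seqs), truth


def write_alignment(alignment: CodonAlignment, path: str | Path,
                    wrap: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.ids, alignment.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")
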