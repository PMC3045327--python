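# aedsx

Sequence analyses of the *Aedes aegypti* *doublesex* (*Aeadsx*) locus —
the double-switch gene at the bottom of the mosquito somatic
sex-determination cascade, whose female- and male-specific transcripts
arise by alternative splicing of sex-specific exons.

The package is for people studying splicing regulation and molecular
evolution of insect sex-determination genes. It implements, as a tested
and reusable pipeline, the computations used to characterize such a
locus:

- **Gene models and junction windows** — classified exons from
  GFF3 + FASTA, derived introns, and the standard junction-table windows
  (last 6 exonic / first 16 intronic nt at the donor, last 16 intronic /
  first 6 exonic nt at the acceptor).
- **Splice-site strength** — the acceptor polypyrimidine count
  ("N° of Y": pyrimidines over the 12 Y-consensus positions of the
  16-nt acceptor window), donor matches against the degenerate consensus
  `GTRAGT`, genome-wide consensus estimation (mean ± sd of the Y count),
  and weak-site classification.
- **Cis-element scanning** — IUPAC-degenerate matching for the splicing
  regulators of *dsx* (dsxRE `TCWWCAATCAACA`, NvdsxRE `KGAAGATW`, RBP1
  types A/B, TRA-2-ISS `CAAGR`), purine-rich (PRE) candidate runs, and
  bipartite region summaries with exact tests.
- **Intron repeat density** — NoRE/kb (elements per kb) and REbp
  (percent of intron covered by the repeat-interval union) per intron,
  with sex-specific vs non-sex-specific group comparison.
- **Microsynteny quality** — percent of conserved genes between two
  regions, order inversions and strand flips.
- **Pairwise dN/dS** — Nei–Gojobori counting (pathway-averaged
  differences, stop-aware site counts) with the Jukes–Cantor correction
  `d = −(3/4)·ln(1 − 4p/3)`, over coordinate partitions of a codon
  alignment (e.g. the DSX OD1 domain vs the common and female-specific
  parts of OD2); dN/dS < 1 indicates purifying, > 1 positive selection.
- **Synthetic data** — generators with recorded ground truth for every
  stage: loci with controllable acceptor pyrimidine content and donor
  fidelity, planted motifs, Poisson repeat annotations, and star-tree
  codon alignments evolved at a target ω.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Score the published junction table of the *Aeadsx* gene and call weak
splice sites against the genome-wide acceptor consensus (8.02 ± 2.15
pyrimidines, tabulated from 4688 *Ae. aegypti* introns):

```sh
python analysis/01_junction_strength.py
```

```
exon_id  y_count acceptor_terminal  donor_match  acceptor_weak  donor_weak
      2       12                AG            5          False       False
     3a       10                AG            6          False       False
     3b        9                AG            5          False       False
      4       11                AG            4          False       False
     5a        5                GT            4           True       False
     5b        8                AG            3          False        True
      6       11                AG            6          False       False

Y counts: [12, 10, 9, 11, 5, 8, 11]
weak sites: 1 acceptor(s), 1 donor(s) - both flank exon 5b
gene span 454427 bp; introns 208-274879 bp, mean 64463 bp (~64 kb)
```

Reading: each row is the intron following that exon. The acceptor
preceding the female-specific exon 5b (the "5a" row) has only 5
pyrimidines over 12 scored positions and ends `GT` instead of `AG` — a
suboptimal 3' splice site; the exon-5b donor `gtactg` matches the
`GTRAGT` consensus at only 3 of 6 positions — a weak 5' site. Every
other junction is strong. This is the signature of a regulated
female-specific exon that requires splicing activation.

The other numbered scripts under `analysis/` run the remaining stages
(simulated-locus validation, bipartite cis-element distribution, repeat
depletion in sex-specific introns, microsynteny arithmetic, partitioned
dN/dS) and write their tables under `results/`.

The same stages are available as subcommands of the `aedsx` CLI
(`junctions`, `scan-motifs`, `repeat-stats`, `synteny`, `dnds`,
`simulate`) for running on your own FASTA/GFF3/TSV inputs; every run
writes a JSON run report with record counts and output checksums.

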