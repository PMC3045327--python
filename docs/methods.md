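# Methods

`aedsx` implements the sequence-level computations used to characterize
the *Aedes aegypti* *doublesex* (*Aeadsx*) locus: splice-site strength
statistics, degenerate cis-element scanning, intron repeat density,
microsynteny quality, and partitioned pairwise dN/dS. This note records
the models, the tunable parameters and the design choices made where the
conventions were genuinely open.

## Gene models and junction windows

Exons are classified `common`, `female_specific`, `male_specific` or
`utr`; classes live in a sidecar JSON keyed by exon ID (an `exon_class`
GFF3 attribute is also accepted) to keep the GFF3 dialect-neutral.
Coordinates are 0-based half-open internally and 1-based inclusive at
the GFF3 boundary. Introns are the gaps between transcription-adjacent
exons; a zero gap is an error, not an empty intron. An intron is flagged
sex-specific when either flanking exon is sex-specific (the predicate is
a function argument and can be replaced).

Each intron carries four junction windows: the last 6 exonic nt and
first 16 intronic nt at the donor, the last 16 intronic nt (ending at
the terminal dinucleotide) and first 6 exonic nt at the acceptor. On the
minus strand windows are read from the reverse complement so the donor
always starts at the transcriptional 5' end. Windows shortened by a
short exon or a contig edge are kept and flagged `truncated`; scoring
rejects them.

A junction-table row convention is fixed throughout: the row keyed by an
exon describes the intron *following* that exon, so the "exon 5a" row's
acceptor is the 3' splice site preceding exon 5b.

## Splice-site strength

Acceptor strength is the pyrimidine count over the first 12 positions of
the 16-nt acceptor window (positions −16..−5 relative to the exon; the
consensus is `YYYYYYYYYYYYNYag/G`, so positions 13–14 and the terminal
dinucleotide are not scored). This definition reproduces the published
per-intron counts (12, 10, 9, 11, 5, 8, 11); counting all 16 positions
does not. `N` counts as a non-pyrimidine.

Donor strength is the number of the first six intronic nucleotides that
fall in the IUPAC set of the consensus `GTRAGT`. The literature also
cites `GTRAGY`; both are supported, with `GTRAGT` the default because it
matches the tabulated consensus row and the published 3/6 score for the
exon-5b donor `gtactg` (which is the same under either form).

The genome-wide acceptor consensus is the mean ± sd of the Y count over
many intron windows; for *Ae. aegypti* the published tabulation over
4688 introns gives 8.02 ± 2.15, and that pair is the default
classification input. The sample (n−1) standard deviation is used; at
n = 4688 the difference from the population form is negligible.

Weak-site calls: an acceptor is weak when its terminus is not `AG` or
its Y count falls below `mean − k_sd·sd` (default `k_sd = 1`, i.e.
below 5.87 for the *Aedes* consensus); a donor is weak when it does not
begin `GT` or matches fewer than `donor_min_match = 4` of 6 consensus
positions. Neither threshold is published; these defaults are the
weakest conditions that single out exactly the exon-5b acceptor (5 Y,
`GT` terminus) and the exon-5b donor (3/6) while leaving every other
tabulated site strong, and both are CLI flags.

## Cis-element scanning

The bundled catalogue carries the five elements relevant to
female-specific *dsx* splicing regulation: dsxRE (`TCWWCAATCAACA`,
13 nt), NvdsxRE (`KGAAGATW`, 8 nt), RBP1 types A (`DCADCTTTA`) and B
(`ATCYNNA`), and TRA-2-ISS (`CAAGR`). The *Bombyx* CE1 element is
20 bp but its sequence is not available here; users must supply it in a
catalogue JSON. Matching is position-wise IUPAC set membership with a
mismatch budget (default 0) on the forward strand (default), since the
published annotations are on the sense strand; both-strand scanning
reports reverse hits in forward coordinates. All overlapping hits are
reported; clustering (hits within a 50-nt gap by default) is a
downstream summary, not a mask. Mapping the *Aedes* TRA/TRA-2 sites with
the *Drosophila* consensus requires `max_mismatch >= 1`, since the
*Aedes* copies deviate in their first four bases.

Purine-rich elements (PRE) have no published consensus, so PRE
candidates are maximal purine runs: pure A/G stretches of at least
10 nt by default, or merged windows above a configurable purine
fraction. They are labeled candidates throughout.

Region summaries count hits per (motif, region) and compare two
designated regions with Fisher's exact test on the 2×2 table of
hit-bearing versus non-hit-bearing start positions — the simplest
defensible quantification of "almost exclusively present in one exon",
which the source analyses state only qualitatively. The chance
expectation per region is `(L − m + 1)·∏ P(position i matches)` under a
uniform (or supplied) base composition.

## Intron repeat density

`NoRE/kb` is the number of annotated repeat elements overlapping an
intron (any ≥ 1 bp overlap counts once) per kb of intron; `REbp` is the
percent of intron nucleotides covered by the union of clipped repeat
intervals, so it can never exceed 100%. Whether the original CENSOR
tables were overlap-merged is unknown; a `--sum-coverage` switch
reproduces raw summation. Reports round NoRE/kb to 2 decimals and REbp
to the nearest percent, mirroring the published precision ("0.6",
"7%"). REbp is invariant under splitting a feature into abutting
pieces; NoRE/kb is not — both behaviours are tested. Group comparison
reports arithmetic means per group (sex-specific versus not) and
per-intron deviation from the non-sex-specific mean; no significance
test is asserted because the original comparison was descriptive.

## Microsynteny

Synteny quality is the percent of conserved genes among the genes of two
regions. The published arithmetic (10 homologues of a printed 16-gene
total → 62%) is inconsistent with a literal two-region reading (10
pairs = 20 genes > 16), so two conventions are exposed:
`pairs_over_printed_total` (default; |pairs| over a supplied total) and
`pairs_over_combined_total` (2|pairs| / (|A|+|B|), symmetric in the two
regions). Reported percentages use round-half-even, which maps
62.5 → 62 as conventionally printed (half-up would print 63). Order
conservation counts discordant pairs (Kendall-style inversions) after
sorting pairs by position in region A, and flags strand disagreements
per pair.

## dN/dS (Nei–Gojobori with Jukes–Cantor correction)

Per codon, synonymous sites `s` are the per-position fraction of
single-nucleotide changes that preserve the amino acid, and `n = 3 − s`.
Changes creating stop codons are excluded from the possible-change
denominator by default, matching the dominant modern implementation of
the method; `--strict-ng86` restores the original 3-change denominator
(stop-creating changes counted non-synonymous), since the exact variant
behind the published analysis is unknowable. Differences between codons
differing at k positions are averaged over the k! single-step orderings,
discarding orderings that pass through stops (kept only when none
survive); `sd + nd = k` always.

Per pair, `S` and `N` are averaged over the two sequences' site counts,
`pS = Sd/S` and `pN = Nd/N`, and `d = −(3/4)·ln(1 − 4p/3)` corrects each
proportion; `p ≥ 3/4` is reported as `saturated`. Codons containing a
gap, `N`, or a stop in either sequence are dropped pairwise (complete
deletion is not used; the original choice is unstated). Pairs with
`dS = 0` are excluded from ratio means and counted, rather than treated
as infinite. The headline per-partition number is the mean of per-pair
dN/dS ratios over `ok` pairs ("mean pairwise ratio"); the ratio of mean
rates is reported alongside. The genetic code is the standard nuclear
table (table-driven and swappable). Partitions are named lists of
1-based inclusive CDS ranges that must respect codon frame, e.g. an OD1
domain partition joined from two ranges versus the common and
female-specific parts of OD2.

Real-sequence reproduction of the published 15-taxon figures is out of
desk scope (it would require downloading the GenBank accessions); the
method is instead validated by oracle equivalence on all 61 sense codons
and by simulation recovery (below).

## Synthetic data generator

Every generator is a pure function of (config, seed); a seed is
mandatory and reruns are byte-identical.

- **Locus**: exon/intron layout from the config; acceptor windows built
  position-wise with each of the 12 Y positions pyrimidine with
  probability `p` (C/T and A/G chosen uniformly within class), terminal
  dinucleotide `AG` unless configured; donors built from `GTRAGT` with
  the first `fidelity` positions forced to match and the rest forced to
  mismatch, so the donor score equals the fidelity. Introns must be at
  least 32 nt to host both windows. Backgrounds are uniform over ACGT;
  the real *Aedes* genome is AT-rich, but the uniform default keeps the
  chance-hit expectations analytically exact.
- **Motif planting**: literal words drawn uniformly from the IUPAC
  expansion, placed at explicit or uniformly drawn non-overlapping
  offsets, with the truth record carrying (motif, start, word).
- **Repeats**: per-intron element counts Poisson at the configured
  density per kb, uniform starts, geometric lengths with the configured
  mean, clipped at intron ends.
- **Codon alignments**: star tree from a random stop-free ancestor; per
  branch, Poisson-many proposed single-base events (default 0.25 per
  codon per branch); stop-creating proposals are rejected, synonymous
  proposals always accepted, non-synonymous ones accepted with
  probability ω. This acceptance-probability ω is a simulation device,
  not a claim about the real substitution process; at these divergences
  the NG86 estimate recovers it closely (within ±0.1 at ≥ 300 codons,
  averaged over 20 replicates, for ω between 0.05 and 1).

What the generator does **not** emulate: between-intron variation in
pyrimidine content (each window uses a single `p`, so the simulated
between-intron sd of the Y count, ≈ 1.63 at p = 0.668, is smaller than
the 2.15 observed in the real genome tabulation, which is
overdispersed); repeat sequence structure (annotations only, no
transposon sequence model); non-star phylogeny; base-composition skew
unless configured. Tests passing on this generator therefore demonstrate
correctness of the computations and recoverability of planted signal,
not distributional realism of mosquito genomes.

## Problem sizes and numerics

The validation suite uses the sizes at which the statistics are stable:
4688 windows for consensus recovery (the real tabulation size), 100
introns of 50 kb for repeat-density recovery, 1000 random fixtures for
the scan and coverage oracles, 200 seeded sequences for chance-hit
rates, and 10–20 replicates of 150–500 codons for ω recovery; simulation
checks use 3-standard-error bounds. Floating-point comparisons in tests
use relative tolerances via `pytest.approx`; interval arithmetic is
exact integer arithmetic throughout. Analysis script 02 uses intron
sizes scaled down ~100× from the published locus (same layout) so the
fixture remains a small text file.

## Known limitations

- Weak-site thresholds are calibrated to reproduce the published calls
  on one locus; they are defaults to start from, not genome-wide
  validated cutoffs.
- The motif scanner verifies and maps known elements; it does not
  rediscover elements de novo (the original discovery used local
  multiple alignment).
- dN/dS is pairwise counting, not tree-aware ML; site-specific ω and
  branch models are out of scope.
- Repeat discovery, homology inference and multiple sequence alignment
  are upstream inputs, not computations of this package.
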