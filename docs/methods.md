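# Methods

## Overview

markerpeek screens prokaryotic genome and metagenome sequencing reads by
targeted assembly of a small set of conserved marker genes. Instead of
classifying every read against a comprehensive database, the pipeline
(1) recruits the tiny subset of reads homologous to 16S, recA, rpoB and
groEL (plus 18S/RAD51/HSP60/RPB2 for eukaryotic contamination), (2)
assembles each gene's reads into contigs, (3) assigns taxonomy to each
contig or leftover singlet by the top bit-score hit against the full
reference set, and (4) tabulates abundance per gene and overall. Because
contigs approach complete genes, species-level calls are far more
reliable than per-read classification of 30–1000 bp fragments, and the
whole computation touches only a few percent of the input.

## Alignment statistics

All searches use optimal Smith–Waterman local alignment with affine
gaps (a gap of length L scores `gap_open + L·gap_extend`). Nucleotide
scoring is match +1 / mismatch −2, gaps −5/−2, with Karlin–Altschul
λ = 0.625, K = 0.41; protein scoring is BLOSUM62 with gaps −11/−1,
λ = 0.267, K = 0.041 — the conventional BLAST-family constants, which
make the pipeline's E-value thresholds meaningful. Raw score S becomes
`S' = (λS − ln K)/ln 2` bits and `E = m·n·2^(−S')`, where m is the
query length (in residues of the aligned molecule) and n the summed
length of the gene's searched set. No edge-effect length adjustment is
applied; for the short queries and small marker databases involved this
shifts E-values by far less than the orders of magnitude separating
hits from the 1e−5/1e−10 thresholds. Traceback ties prefer diagonal,
then up, then left, and tied maximal cells resolve to the smallest
query/subject index, so alignments are bit-for-bit reproducible.

Reads hitting protein markers are aligned through all six translation
frames (bacterial/plastid code, table 11); the best intact frame
carries the hit. This approximates frameshift-corrected translated
search: a read with an internal indel is scored by its longer
correctly-framed segment, which for 101 bp reads passes the recruitment
thresholds whenever roughly 60 bp of intact coding sequence remains.

## Recruitment

A read joins a gene's bin iff its best hit against that gene's
non-redundant reference set has E < 1e−5 and identity > 0.80, both
strict. Identity is measured on the columns actually aligned —
nucleotide columns for rRNA genes, amino-acid columns for protein
genes. Reads are stored reverse-complemented when the best hit is on
the minus strand, so downstream assembly sees a consistent orientation.
An exact k-mer prefilter (k = 11 nucleotide, k = 5 amino acid, per
frame) gates the full dynamic programming; k = 5 keeps the false-pass
rate of random translated frames at a few percent while exact 15 bp of
in-frame agreement with any reference suffices to pass, which
error-free and 1%-error reads essentially always have. The prefilter is
a stand-in for a seeded search engine, not part of the result contract:
recruitment with `use_prefilter=False` defines the reference behaviour
and the suite checks both paths agree on fixtures.

## Assembly

Each bin is assembled by greedy overlap-consensus: repeatedly merge the
highest-scoring qualifying ungapped overlap (dovetail or containment)
among the current sequences until none remains. An overlap qualifies at
≥ 20 columns (the published minimum-overlap setting) and ≥ 0.90
identity; candidates rank by identity×length (= match count), then
length, then read id, making assembly deterministic. Consensus is the
per-column majority base, ties to the earliest-placed read. Gapped
overlaps are not modelled — a read whose indel prevents any qualifying
ungapped overlap survives as a singlet and is still classified, which
the pipeline tolerates by design. At a 1% error rate with a 4:1
substitution:indel ratio this routes roughly a fifth of recruited reads
into singlets; their abundance still counts.

For large recruited bins, overlap placement is restricted to a ±16 bp
band around the offset predicted from each read's recruitment anchor
(its start position projected onto the recruiting reference), and only
reads recruited by the same non-redundant representative are paired.
This turns the O(n²·L²) overlap search into an effectively banded one
with no observed effect on results (tested against the exhaustive
search); bins without anchors always use the exhaustive search.

## Classification and tie-breaking

Contigs and singlets are searched against the gene's FULL redundant
set, keeping hits with E < 1e−10 (strict). The contig takes the genus
and species of the top bit-score hit. Bit scores are rounded to 2
decimals before tie detection, emulating report granularity. If the
tied top hits span more than one (genus, species), a secondary
nucleotide search is run against the gene's source nucleotide sequences
(stored alongside every protein record for exactly this purpose) and
tied hits whose genus is absent from that search's top result are
excluded; a residual tie is reported as a multi-genus call with no
species. For rRNA genes the secondary search would repeat the primary
one and is skipped. Contigs with no significant hit are retained as
unclassified.

## Quantification

Abundance of a classified contig = alignment length × number of member
reads. Rows are summed per (gene, genus, species); a multi-genus call
contributes one row per listed genus, species "multiple", with the
abundance split equally (the assignment table keeps the un-split
record). Per-gene fractions normalise within the gene; the overall
table sums raw abundances across genes without per-gene renormalisation
— gene-specific skew is visible in the per-gene tables. Because rRNA
operon copy number varies ~1–15× between genomes, the `exclude_16s`
flag drops 16S/18S from the overall table, leaving the single-copy
protein markers as an unbiased (if less sensitive) abundance basis.

Abundance values are quantized by whole contigs: when a low-abundance
species' genes assemble incompletely, its rows under-represent it, and
the transition to full-length contigs moves shares in visible jumps.
For contamination screening the package therefore also reports the
classified-read share per genus (`classified_read_share`): every contig
contributes its read count to its assigned genus. This
percentage-of-sequences view tracks read origin directly, varies
smoothly with the true contaminant fraction, and is the quantity the
contamination-series tests assert on. Its residual background — short
error-bearing singlets or two-read contigs whose best local alignment
lands on the wrong species — measures at the few-hundredths-of-a-percent
level under the default 1% read error rate.

## Reference databases

Reference FASTA headers carry taxonomy as
`>record_id|genus|species[|strain]`. Curation removes exact duplicate
sequences, records outside a per-gene length window (default
0.5–1.5 × the gene's median length) and records with > 5% ambiguous
residues — a reproducible stand-in for manual curation. Split rpoB
fragments (B′/B″) are concatenated using an explicit caller-supplied
pairing. The non-redundant search set comes from greedy longest-first
clustering at 90% identity, where identity is measured over the shorter
sequence (1 − infix edit distance / shorter length, computed with
edlib); global-over-shorter is the CD-HIT convention, fixed here and
verified against a brute-force oracle in the tests.

## Synthetic data

The simulator defines the study conditions used throughout the tests:

- reads: length 101, uniform start and strand; error count per read
  ~ Binomial(101, 0.01) by default; error positions drawn independently
  with density ∝ 1 + x⁴ of relative position (errors grow toward the
  3′ end); each error is a substitution with probability 4/5, else a
  1 bp insertion or deletion (equiprobable). The 101 bp length and 4:1
  ratio are the two published simulation parameters; the total rate and
  polynomial are configurable defaults chosen as typical Illumina-like
  values.
- references: two (or more) species at 10% pairwise marker divergence
  by default, each species' copy carrying divergence/2 substitutions
  from a random ancestor; protein markers are stop-free ORFs mutated
  codon-aware. Gene lengths default to 16S 1500, recA 1059, rpoB 3501,
  groEL 1647 bp — realistic full-length sizes.
- genomes: the species' markers (16S at a configurable copy number)
  embedded at random positions in random background totalling 50 kb.
  Real genomes are 40–100× larger; shrinking the background raises the
  recruited fraction so that 20 000-read files give usable marker
  coverage at desk scale. Genome layout draws from a per-species RNG
  stream, so changing one species' 16S copy number leaves every other
  sequence untouched.
- mixtures: read counts per component are exact (largest-remainder),
  so a contamination series (0–5% by 1%, then 5% steps to 100% — 25
  files) has no file-level sampling noise; within-file placement noise
  remains.

What the generator does not emulate: quality-score structure (constant
Q30 placeholders), paired ends, platform-specific artefacts
(homopolymer errors, adapter read-through), real phylogenetic structure
(divergence is uniform rather than clock-like), intra-species strain
variation, and conserved-core versus variable-region structure within
genes. Passing tests therefore demonstrate the pipeline's logic and its
behaviour under a controlled error model, not performance on real SRA
data, where curation quality and database completeness dominate.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open everywhere; minus-strand hits report
subject intervals on the forward subject and query intervals on the
oriented (reverse-complemented) query. `N` never matches anything,
including itself. Empty read files yield empty tables and a warning,
not an error. An empty hit list classifies as "unclassified" and
contributes zero abundance. Equal-scoring mixture components and
consensus ties resolve by input order. All randomness flows through
numpy Generators seeded from explicit arguments.

## Known limitations

- The six-frame approximation under-recruits reads whose indel sits
  near the middle of their coding overlap; they are lost rather than
  frameshift-corrected.
- Ungapped overlaps make assembly split around indel-bearing reads,
  inflating singlet counts at high error rates.
- Cross-species read absorption into the dominant species' contigs
  (the weighted-assembly bias the method inherits from its design)
  attenuates low-abundance contaminant estimates, most strongly for
  16S when two species sit near the 90% overlap-identity boundary;
  protein-only tables give the cleaner contamination signal.
- Abundance is alignment-length-weighted, so one species assembled
  into long contigs outweighs the same read count left as singlets.
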