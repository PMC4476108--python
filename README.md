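# markerpeek

Marker-gene targeted assembly for rapid taxonomic screening of
prokaryotic genome and metagenome sequencing reads.

## The problem

Whether you are checking a freshly sequenced isolate for contamination
or profiling a metagenome, the first question is *which species are in
these reads?* Classifying every read against a comprehensive database
is slow, and short reads (30–1000 bp) carry too little signal for
reliable species-level calls. markerpeek takes the targeted-assembly
route: it extracts only the reads homologous to a small panel of
universally present, taxonomically informative genes — 16S rRNA,
*recA*, *rpoB* and *groEL* (plus 18S/*RAD51*/*HSP60*/*RPB2* to flag
eukaryotic contamination) — assembles them into contigs approaching
complete genes, and classifies the contigs instead of the reads. A few
percent of the input does all the work, and near-full-length genes make
species-level assignment far more specific.

## Method in brief

1. **Recruit.** Each read is aligned (Smith–Waterman; both strands for
   rRNA genes, six-frame translated for protein genes) against a
   non-redundant reference set (greedy clustering at 90% identity).
   A read is kept iff its best hit has E-value < 10⁻⁵ and identity
   > 80%, with `E = m·n·2^(−S′)` and `S′ = (λS − ln K)/ln 2` bits.
2. **Assemble.** Per gene, a greedy overlap-consensus assembler merges
   the highest-scoring qualifying overlap (≥ 20 bp, ≥ 90% identity)
   until none remains; unmerged reads survive as singlets.
3. **Classify.** Contigs and singlets are searched against the full
   redundant set (E < 10⁻¹⁰); each takes the genus/species of the top
   bit-score hit. Ties across genera trigger a secondary nucleotide
   search whose top hit excludes foreign genera; residual ties are
   reported as multi-genus calls.
4. **Quantify.** Abundance per contig = alignment length × member read
   count, tabulated per (gene, genus, species) and overall. Because
   genomes carry 1–15 rRNA operon copies, `--exclude-16s` drops
   16S/18S from the overall table; `classified_read_share` gives the
   complementary percentage-of-sequences view used for contamination
   screening.

A built-in simulator (Illumina-like 101 bp reads, binomial error count,
position-dependent error density, 4 substitutions per indel, exact
ground truth) and a synthetic reference generator make the entire
pipeline testable offline; see `docs/methods.md`.

## Worked example

```python
from markerpeek import (make_synthetic_references, build_reference_db,
                        ReadSimProfile, MixtureSpec, make_mixture,
                        PipelineParams)
from markerpeek.quantify import analyze_reads

# two synthetic species, markers 10% divergent, 50 kb genomes
records, genomes = make_synthetic_references(2, 0.10, seed=1)
db = build_reference_db(records, clean=False)

# a 98:2 mixture of 20,000 101-bp reads at 1% error
profile = ReadSimProfile(n_reads=20_000, total_error_rate=0.01, seed=3)
reads, _ = make_mixture(genomes, MixtureSpec([("sp0", 0.98),
                                              ("sp1", 0.02)]), profile)
table, assignments = analyze_reads(reads, db, PipelineParams())
print(table.overall)
```

prints

```
    genus   species  abundance  fraction
0  Genus0  species0  2157552.0  0.998277
1  Genus1  species1     3723.0  0.001723
```

The dominant species carries almost all marker abundance; the 2%
contaminant shows up as a clearly nonzero second row. Abundance-
weighted estimates under-represent low contaminants because their genes
assemble into shorter contigs; the classified-read share
`classified_read_share(assignments)` tracks the mixing fraction
directly (here 0.982 / 0.018 against a true 0.98 / 0.02 split). The
same analysis is available from the shell:

```bash
markerpeek simulate --n-species 2 --n-reads 20000 --out demo
markerpeek run --reads demo/reads.fastq --db demo/db --out demo/out
```

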