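# Methods

This note records the models, parameter choices and numerical conventions
behind `gbsmut`, and what the simulation-based tests do and do not
demonstrate about real data.

## The analysis problem

A mutagenized plant population is genotyped by reduced-representation
sequencing: the genome is cut with restriction enzymes, fragments in a size
window are sequenced, and a multi-sample variant call set is produced. Two
features dominate the analysis design. First, GBS coverage is shallow and
strongly uneven across samples and sites, so raw genotype calls contain many
dropouts and miscalled heterozygotes. Second, the non-mutagenized material is
not isogenic: the wild-type panel carries its own segregating variation, so
"differs from wild type" is not a usable definition of an induced mutation.
The pipeline answers both with (a) a rule-based genotype filter tuned to GBS
error modes and (b) a consensus restricted to positions where *all* wild-type
accessions agree on a homozygous genotype, against which mutant genotypes are
compared.

## Genotype filter

Per-sample rules run first, then site rules on the adjusted calls.

* Depth rule: a genotype supported by fewer than `min_sample_depth = 8` reads
  is set missing.
* Allele balance: for a heterozygote, AB = alt depth / (ref + alt depth).
  AB < 0.20 reverts the call to hom-ref, AB > 0.80 to hom-alt; the band
  endpoints are inclusive (reversion only when strictly outside). AB is
  oriented to the alternate allele. A heterozygote without usable AD skips
  the rule and is counted in the tally.
* Site rules, first failing rule reported: (a) at least two distinct alleles
  among non-missing calls; (b) non-missing calls in at least 66% of the
  *manifest* samples (all samples, not just those with data; no rounding to
  integer counts); (c) depth summed over non-missing calls ≥ 20; (d) each
  allele's AD summed over non-missing calls ≥ 10; (g) sites where every
  non-missing call is heterozygous are excluded.

Threshold edge semantics are "keep iff ≥": a site with summed depth exactly
20 or per-allele depth exactly 10 passes. Site aggregates (rules c, d) are
computed over the calls that survive the per-sample rules; a call zeroed by
the depth rule contributes nothing. Multiallelic records are decomposed to
biallelic records before filtering; a genotype referring to a different alt
allele becomes missing in the decomposed record, and AD is reduced to the
(ref, this-alt) pair.

The filter is idempotent and monotone: re-filtering its own output changes
nothing, and tightening any threshold never increases the kept-site count on
a fixed input (verified on randomized matrices against an independent
per-rule reference implementation).

## Consensus and induced-mutation calling

A filtered site enters the consensus iff every wild-type sample has a
non-missing call, all wild-type calls are identical, and the shared genotype
is homozygous (hom-ref or hom-alt); shared heterozygous sites are excluded,
consistent with the upstream het-only exclusion. Each (mutant × consensus
position) pair is then classified: missing or below the 8-read cutoff →
*removed* (reason `low_depth` when depth < 8, else `missing`); identical to
the consensus genotype → *consensus-equal*; anything else → *induced*. The
bookkeeping identity induced + equal + removed = positions × mutants holds
for every run and is asserted in the tests. Induced calls are not re-checked
for allele balance beyond the upstream filter, and positions outside the
consensus are ignored entirely.

## Effect annotation

Gene models are single-transcript, CDS-only (no UTRs); GFF3 is written and
read 1-based inclusive and converted internally to 0-based half-open. A
coding SNP is classified by translating the reference and alternate codons
(strand- and phase-aware, standard nuclear code): same residue → synonymous;
new internal stop → stop gained; lost terminal stop → stop lost; damaged
initiator ATG → start lost; otherwise non-synonymous. A coding indel is a
frame shift when its length is not a multiple of three, else a codon
insertion/deletion. Intronic positions within `splice_region = 2` bases of an
exon boundary are splice donor (intron 5′ end in transcription orientation)
or splice acceptor (3′ end); flanking positions within the strand-aware
`upstream_window`/`downstream_window` (both default 5000 bp — the windows are
a convention, not an externally fixed value) are upstream/downstream;
everything else is intergenic. A variant overlapping several genes yields one
annotation per gene; a most-severe-per-variant view is also provided with
severity order stop gained > stop lost > start lost > frame shift > splice >
codon ins/del > non-synonymous > synonymous > intron > up/downstream >
intergenic. Per-category summaries count occurrences and distinct genes, with
intron and intergenic rows reporting zero distinct genes by convention.

Substitution spectra use the six unordered base-pair classes labelled C/T,
A/G, C/G, A/T, A/C, G/T with no strand collapsing; transitions are {A,G} and
{C,T}; the Ts/Tv ratio is reported to one decimal and flagged undefined when
no transversions are observed.

## In-silico digestion

Recognition sites are IUPAC patterns matched on both strands (the built-ins —
MslI `CAYNNNNRTG` cut at 5, PstI `CTGCAG` cut at 5, MspI `CCGG` cut at 1 —
are their own reverse complements, so a top-strand scan covers both); N in
the subject never matches. Fragment boundaries use top-strand cut coordinates
only; overhangs are ignored for interval arithmetic because size selection
operates on approximate lengths. Every match is cut (no site-exclusion logic
for overlapping sites). A site containing a methylated cytosine in one of the
enzyme's blocking contexts is not cut; PstI defaults to CHG (CpNpG) blocking,
MslI and MspI to none (an MspI variant with CpG blocking can be constructed
for sensitivity analyses). Size selection keeps fragments with
200 ≤ length ≤ 500 (inclusive); the ddGBS `rare-common` rule additionally
requires one end from each enzyme, terminus ends never qualifying.

One geometric subtlety: reverse-complementing a contig preserves the full
fragment-length multiset only for centered (blunt) cutters like MslI. For
off-center cutters every cut shifts by |2c − L| relative to the mirrored
coordinate, so internal fragment lengths are invariant while the two terminal
fragments trade that offset. The tests assert exactly this.

## Read QC

Rules run in a fixed order — N content, raw length (< 20 bases), 5′ residual
restriction site (IUPAC match; e.g. `TGCAG` for PstI, `CGG` for MspI,
`NNRTG` for MslI), 3′ quality trim, trimmed length (< 64 bases) — cheapest
checks first, and the reported discard reason is the first failing rule.
Quality trimming strips the maximal 3′ suffix of bases below the Phred
threshold (default Q20, configurable; a simple cutoff, not a sliding
window — the threshold is this package's choice, as the procedure it
implements specifies no value). Paired-end mates are filtered independently;
by default a pair survives only if both mates pass.

## Synthetic cohort model

The generator emulates the study conditions the pipeline targets.

* Panel: 14 wild-type + 82 mutant samples (96 total).
* Reference: 2 × 200 kb contigs at GC 0.36 (a plant-nuclear-genome-like
  value), 40 genes with valid ORFs (ATG start, no internal stops, GT…AG
  introns, 1–3 exons, 100–300 codons) placed without overlap.
* Reduced representation: variants are only planted inside 200–500 bp
  MslI fragments, emulating what a GBS library can see.
* Variant layers: background variants (rate 1e-3 per callable base) shared
  verbatim by all 96 samples, half heterozygous, half hom-alt; private
  wild-type variants (2e-4 per callable base per accession) that make the
  consensus step non-trivial; and per-mutant EMS mutations, Poisson with
  mean 20, heterozygous (M1-generation material), each a directed G→A or
  C→T transition with probability 0.678 and otherwise a uniform draw from
  the remaining substitution classes. The background and private rates have
  no external anchor; they are plausible round numbers chosen once.
* Sequencing model: per-sample per-site depth ~ negative binomial
  (mean 30, dispersion 5 — GBS libraries are strongly overdispersed; the
  data being emulated fix no depth model); heterozygote alt depth ~
  Binomial(depth, 0.5); homozygote off-allele depth ~ Binomial(depth,
  base_error_rate = 0.005); genotypes drop out at missing_rate = 0.05 with
  depth set to 0.
* Methylation: top-strand cytosines in CpG context methylated at rate 0.6
  (heavily methylated plant genome) and CHG at 0.3.
* Determinism: one global seed; per-stage generators derived as
  `default_rng([seed, stage])`; identical configurations give byte-identical
  FASTA/VCF/FASTQ output.

Variant positions are drawn uniformly *without replacement* across layers, so
no two planted variants share a position. This keeps the ground truth
unambiguous, at two costs: mutation hotspots/recurrent sites do not occur,
and hom-alt consensus positions are essentially absent from simulated runs
(they would require mutant variation at a position where the wild types share
a homozygous alternate genotype, a configuration distinct-position drawing
never creates). The consensus code handles hom-alt sites; they are exercised
with constructed call sets rather than simulated ones.

Read simulation emits one 100 bp pair per size-selected fragment whose ends
were enzyme-cut, starting at the near-side strand cut so reads begin with the
residual recognition sequence. A configurable fraction of reads is damaged,
split evenly across the four QC failure modes, to exercise every
preprocessing rule. Alignment is not simulated; the cohort call set is
emitted directly as the multi-sample VCF a caller would produce downstream.

## What the tests show — and do not

With the default conditions the pipeline's recall and precision for EMS
mutations *at consensus positions* are ~1.0. This is partly structural:
an EMS site whose single carrier drops out (or is reverted to hom-ref) no
longer shows two alleles and is removed by the filter before consensus
building, leaving the consensus denominator enriched for recoverable sites.
The simulation therefore demonstrates internal consistency of the chain —
bookkeeping, rule semantics, spectrum recovery within binomial error — not
performance on real data, where alignment artefacts, paralogy, multi-carrier
sites and caller-specific genotype errors (none of which are modelled) set
the effective error floor. Genotypes in the simulator are truth-derived;
only depths carry noise, so the filter's reversion rule is exercised by
sampling noise in allele depths rather than by systematic caller error.

## Numerical conventions and degenerate inputs

* Coordinates: VCF and GFF3 are 1-based; BED and all internal intervals are
  0-based half-open.
* Ties: when two enzymes cut at the same coordinate the first enzyme listed
  labels both ends.
* Zero transversions → Ts/Tv reported as undefined rather than infinite.
* Empty fragment set → read simulation warns and returns nothing; empty
  FASTQ → empty output with zero totals; a cohort whose genome yields no
  size-selected fragments is a configuration error.
* Genes that cannot fit their contig slot raise a configuration error naming
  the contig.
* Problem sizes in the test-suite and acceptance runs (80–400 kb genomes,
  10 simulation seeds, 200 random 50 × 10 filter matrices) were chosen to
  make the statistical bounds tight at interactive runtimes.
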