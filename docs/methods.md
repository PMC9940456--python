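# Methods

## The map-then-assemble model

`panforge` assumes a panel of individuals resequenced with paired-end short
reads and a single linear reference genome. Sequence private to some
individuals (the dispensable genome) cannot map to the reference; it
surfaces as read pairs that are unmapped or improperly paired. The pipeline
assembles that fraction per individual, reduces the cross-individual
redundancy of the resulting contigs, and places each non-redundant contig
back onto the reference using the pairing information of reads that bridge a
contig end and a chromosome. The underlying geometric assumption is that a
novel insertion has unique flanking sequence on the reference, and that the
insert-size distribution bounds how far a bridging mate can land from the
insertion breakpoint: with insert mean μ and read length L, mates of
contig-end reads fall within roughly μ of the breakpoint, so the mate
positions of a genuine insertion cluster tightly (the < 2 kb span rule) and
sit on both sides of it (the two-end merge rule).

## Stage parameters

| Stage | Parameter | Default | Why |
|---|---|---|---|
| triage | mode | not-proper-pair | `-F 2` semantics; recruits discordant-but-mapped pairs, whose unmapped mates let assembly reach the breakpoint junctions |
| assembly | k | 63 | odd neighbour of the common 64 (canonical k-mers need odd k to avoid palindromes); must stay below read length |
| assembly | min_kmer_count | 2 (library) / 3 (pipeline) | see "Error control" below |
| assembly/filter | min contig length | 300 bp | contigs shorter than 300 bp are discarded |
| dedup | identity | 0.80 | greedy clustering gate; identity = matches / shorter sequence under best placement, both strands |
| dedup | length ratio | 0.95 | shorter/longer length ratio required for cluster membership |
| anchor | end_window | 300 bp | contig-side reads must start in the first, or end in the last, 300 bases |
| anchor | min_support | 10 reads | minimum bridging mates per locus |
| anchor | min_mapq | 10 | applied to the contig-side read (a flag extends it to both mates) |
| anchor | max_span | 2 000 bp | mate positions of one locus must span strictly less than this |
| anchor | merge_distance | contig length + 2·max_span | two-end loci merge within this gap; a geometric bound on how far apart the two flanking mate clouds can sit |
| validate | identity / coverage / min alignment | 0.90 / 0.80 / 300 bp | alignment gates against an independent assembly; gates are inclusive (≥) at the boundary |
| validate | flank length / tolerance | 1 000 / 2 000 bp | flank realignment concordance window |

All in-memory coordinates are 0-based half-open; conversion to 1-based
happens only at SAM ingestion (pysam) and CSV export (1-based inclusive,
noted in the file's header comment). BED output is 0-based half-open.

## Error control in assembly

The unitig assembler has no bubble popping or tip clipping; the k-mer count
floor is its only error control, so the floor must be chosen against the
sequencing depth. A substitution error recurring identically in two reads
(same genomic position, same alternate base) creates a duplicated error
k-mer that branches the graph and breaks the unitig. At depth d and
per-base error rate e, such duplications occur at a rate of roughly
C(d,2)·e²/3 per base — at 30× and 0.5% that is ~0.004/bp, i.e. dozens of
breaks across a few tens of kilobases of novel sequence. A count floor of 3
pushes the rate to ~5·10⁻⁵/bp while true k-mers (expected multiplicity
≈ d·(1−e)^k ≈ 22 at 30×) are untouched. The pipeline therefore defaults to
`min_kmer_count: 3` (a noise floor of about depth/10); the bare
`AssemblyParams` default stays at 2, appropriate for ≥ 20× panels with lower
error, and 1 is the right choice for error-free unit-test input.

### What is assembled

By default the assembler consumes only the *unmapped members* of the
selected pairs (`assembly.unmapped_reads_only: true`). The mapped mates of
discordant pairs are reference sequence by definition; including them pads
every contig with several hundred bases of reference flank whose depth
decays with distance from the breakpoint. Those flank stubs (i) push the
insertion junction out of the 300 bp anchoring end-window, so reads bridging
the junction no longer count as contig-end evidence, (ii) vary in length
between individuals, defeating the 0.95 length-ratio gate so that contigs of
a shared insertion fail to co-cluster, and (iii) occasionally assemble into
flank-only contigs with no novel content. With unmapped-only input the
flank overhang is bounded by one read length (only junction-spanning reads
contribute it) and all three artefacts disappear. The mapped mates are still
written to the triage FASTQ so a pair-aware external assembler can use them.

## Locus calling

Bridging mates are grouped by (contig, contig end, chromosome) and their
chromosomal positions sorted. A two-pointer sweep finds every maximal run
with span strictly below `max_span`; runs holding at least `min_support`
positions qualify, and overlapping qualifying runs merge into a single locus
reported as [min position, max position]. This is deterministic and is
tested against brute-force enumeration of all windows. After locus calling,
a FIRST-end and a LAST-end locus on the same chromosome merge (nearest pairs
first, each locus at most once) when their gap is at most the merge
distance. The status partition is then mechanical: one locus → unique,
several → multiple, none → unplaced. When both ends anchor, the relative
order of the FIRST and LAST loci gives the contig's orientation.

Evidence from all provided alignment files is pooled before thresholding, so
an insertion shared by several individuals accumulates support jointly; a
read whose contig-side alignment falls in both end windows (contig < 600 bp)
counts once per end but never twice at one end. Secondary and supplementary
alignments are excluded from evidence by default.

## Filtering and clustering conventions

The filter cascade is order-fixed (length → vector → taxon/organelle), each
stage a pure filter, so the cascade is idempotent and the report counts
reconcile exactly. The vector screen collapses the classic match-strength
categories to one gate — an ungapped seeded local match of ≥ 30 bp at ≥ 90%
identity on either strand — which suits adapter contamination (near-exact,
indel-free). Taxonomic screening consumes a precomputed tabular hit file
(BLAST outfmt-6 plus a taxon-label column); the best hit per contig is the
maximal bitscore, ties broken by identity and then the lexicographically
first target. Contigs with no hits are kept: removal requires positive
evidence of alien origin.

Clustering follows the greedy incremental scheme: contigs in decreasing
length order (ties by id), first-fit assignment to the earliest-founded
representative passing both gates. Identity is computed as an infix
edit-distance alignment of the shorter sequence inside the longer (edlib
backend), 1 − d/|shorter|, maximised over strands; this matches the
global-identity convention of greedy clustering tools at these thresholds.
An 8-mer shared-word prefilter skips pairs that cannot reach 0.80 identity;
the oracle tests run with the prefilter disabled and also confirm it does
not change outcomes on planted near-duplicate sets.

## The simulator and its truth-aware aligners

The simulator emulates: a uniform-random reference (one or more
chromosomes); per-individual donor genomes that are the reference with novel
segments inserted at recorded positions, where a segment is shared across a
random subset of individuals with a configurable probability (identical
sequence and position in every carrier); paired-end sequencing with uniform
fragment placement, Gaussian insert length truncated at 2·read_length, and
uniform substitution errors (no indels by design — the unitig assembler's
contract is substitution-only input). Novel segments are random sequence
regenerated until they share no 31-mer with the reference, so "novel" is
well-defined and interior reads are guaranteed unmappable. All randomness
flows from a single integer seed through numpy Generator streams; outputs
are byte-reproducible.

Two truth-aware aligners write valid SAM by looking up each read's true
origin (encoded in its name) rather than aligning; they are explicit test
doubles for an external short-read mapper, clearly named, and never used
when real alignments are supplied. Against the reference: a read maps at
its true position (MAPQ 60) iff it lies wholly inside a reference-derived
donor segment; a pair is properly paired iff the whole fragment does.
Against the panreference: reads wholly in reference sequence go to the
chromosome — including flank reads that a contig also carries, mirroring how
a mapper prefers the longer unique context; reads inside a contig's located
donor interval (novel sequence plus assembled junction overhang) go to the
contig; novel-interior reads of *other* carriers of a shared insertion reach
the representative contig through novel-segment coordinates. Contigs are
located on their donor of origin by infix edit-distance alignment on both
strands, accepted below 5% divergence.

What the simulation does **not** emulate — and hence what passing tests do
not show about real data: repetitive genomes (novel segments and the
reference are random sequence, so anchoring flanks are always unique, unlike
transposon-rich insertions), quality-dependent or indel errors, insert-size
outliers and chimeric fragments, mapping ambiguity and MAPQ degradation near
repeats, and biological divergence between carriers of a shared insertion.
Real panels should expect substantially lower unique-placement rates than
the simulation's near-perfect recovery.

## Problem sizes

The default study conditions — 1 Mb reference, 5 individuals, 10 insertions
each of 1–3 kb with sharing probability 0.5, 150 bp pairs at 30×, insert
500 ± 50 bp, 0.5% error — are the package's chosen desk-scale working point:
large enough that every stage sees realistic signal (tens of thousands of
read pairs per individual, shared and private insertions, recurring
sequencing errors), small enough to run end to end in about a minute on one
CPU. Unit tests use smaller genomes (120–200 kb, 2 individuals) with the
same structure.

## Known limitations

* The assembler emits unitigs only: no scaffolding, gap filling, bubble
  popping or tip clipping. Heavily fragmented input (high error, low depth)
  degrades into sub-300 bp fragments that the length filter removes.
* The vector screen is ungapped; an adapter split by an indel inside the
  match would be missed (full gapped screening belongs to the external
  tool whose tabular output the module also accepts).
* Flank-concordance validation evaluates unique placements only; multiple
  placements are reported but not adjudicated.
* Greedy clustering is order-dependent near its thresholds: pairs right at
  0.80 identity may split depending on which founds the cluster. The
  co-clustering guarantee is therefore only asserted (and tested) at ≥ 0.90
  identity.
* CRAM input, BAM writing and quality-aware trimming are out of scope.
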