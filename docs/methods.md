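# Methods

## Coordinate convention

Upstream sequences are stored 5'→3' and indexed with 3'-anchored negative
positions: base −1 is the base immediately 5' of the V-region start (the
last base of the leader exon). All rules in the pipeline — base extraction,
coverage truncation, the −93 analyses — are anchored at the V boundary, so
sequences of different 5' extents compare naturally by their shared 3'
suffix. Most IGHV leaders encode a 19-aa signal peptide (57 nt, initiation
ATG at −57..−55); per-gene overrides handle 20-aa leaders (ATG at −60..−58,
e.g. IGHV3-64).

## Pre-processing

5'-RACE forward reads begin with a random barcode, a `TAC` linker, and a
TdT-derived homopolymeric G-tail. Trimming is exact-match and strict:

* the core motif (`TACGGG`, configurable) must start within the first 40
  bases of the forward read, otherwise the pair is discarded entirely —
  fuzzy rescue of a corrupted adaptor is deliberately not attempted;
* the first motif occurrence wins: the barcode is random, so a spurious
  internal motif further into the insert must not cause over-trimming,
  while the true adaptor always precedes the insert;
* everything through the *maximal* G-run following the linker is removed.
  Library G-tails and biological 5'-terminal Gs are physically
  indistinguishable, so this removes both: a small price that eliminates
  the artefactual "5'-terminal G" variant class. Reads empty after
  trimming are discarded and counted separately.

Mates are then joined by overlap (reverse read reverse-complemented;
largest overlap scanned first; minimum overlap 10, mismatch fraction ≤ 0.1,
both configurable). Pairs that fail to overlap go to a reject stream rather
than being concatenated.

## Filtering

Reads: only `V_errors = 0` rows are used, removing sequencing error, somatic
hypermutation and allele mis-assignment in one cut. Alleles (per subject):
kept when unique CDR3s ≥ 75 counted over *all* entries of the allele (any
V-error count, i.e. before the read filter — the diversity of independent
rearrangements, not of clean reads) and zero-error reads ≥ 20. Both
comparisons are inclusive ("fewer than 75" excludes 74 and keeps 75). Rows
with comma-separated multi-allele V calls cannot be attributed and are
excluded from grouping (counted in the report); rows with empty CDR3 count
as reads but contribute no CDR3.

## Consensus inference

Starting at position −1 and moving 5'-ward, at each position:

1. *coverage*: reads of the current (sub)group that reach the position and
   are not `N` there. If covering/group < 50 %, extension stops; the final
   length is the longest 3'-anchored prefix satisfying this rule.
2. *extraction*: any base carried by ≥ 30 % of covering reads is
   extractable. None → stop (noise with no extractable base). One → extend.
   Two or more (at most three can reach 30 %) → the covering reads are
   partitioned by their base; partitions whose base met the threshold are
   re-analysed from the 3' end as independent subgroups; sub-threshold
   partitions are discarded with a reason code. Partition sizes sum to the
   covering count and no read lands in two subgroups.

The denominator of the 30 % rule is the reads *covering* the position, not
the whole group: reads too short to reach a position carry no evidence
about it, and length is already governed by the separate 50 % rule. Reads
not covering a split position are dropped from both subgroups — they cannot
be attributed, and their evidence was consumed at more-3' positions. Both
choices are configurable-by-design points where reasonable alternatives
exist. Recursion terminates because every split strictly reduces group
size. The emitted set of (sequence, read-count) pairs is invariant under
input permutation, and every record re-satisfies the 30 %/50 % conditions
position-by-position against its own subgroup; an independent brute-force
partitioner is kept in the test suite as the oracle for this walk.

## Consolidation and labelling

Per allele, per-subject sequences that are identical over their overlapping
3'-anchored extent are clustered (longest-first greedy assignment; a record
joins a cluster only if compatible with *all* members, keeping clusters
transitive-safe). Reported length: the largest L with ≥ 80 % of members of
length ≥ L, found among member lengths (the feasible set is a step
function, so the maximum lies at a member length). The quorum counts
sequences, not subjects. Labels A, B, C… are assigned per allele by
descending member count, ties by lexicographic sequence order — a
deterministic but arbitrary scheme that makes no claim of matching any
external letter naming.

Artifact flags (advisory only; nothing is auto-removed): a variant whose
single-base deletion inside a homopolymer run (length ≥ 2) makes it
identical to a sibling variant (sequencing insertion errors concentrate in
homopolymers); a 5' terminus starting with the adaptor motif or a ≥ 3-base
G-run (trimming escape); low unique-CDR3 support when counts are supplied.

## Validation

*Haplotype segregation.* In a subject heterozygous at the anchor J gene
(IGHJ6; both alleles must hold ≥ 10 % of anchor-gene reads), each read is
assigned to a variant when identical over its full 3'-anchored overlap
(≥ 30 bases) with exactly one variant of its allele; ambiguous reads are
dropped. Per-variant read counts split by J allele give purity
max/(sum); ≥ 0.95 validates — strict 1.0 would fail genuinely segregating
variants with single stray reads (e.g. a 1 vs 107 split), which arise from
rare J mis-assignment.

*CDR3-length diversity.* A genuine germline variant is carried by many
independent rearrangements; the histogram of CDR3 amino-acid lengths of its
matched reads makes collapse onto a single clone visible.

*Base −93.* For 92-base upstream regions typical of the IGHV4 subgroup,
reads perfectly matching bases −1..−92 and extending to −93 are counted by
their −93 base (T/G/other) per J-defined haplotype; both counts are always
reported and the ratio is given as T/G (the orientation is a convention,
not a claim).

*Population SNPs.* VCF sites within a region are decomposed to biallelic
records, allele frequency taken from INFO/AF or genotype counting, folded
to MAF = min(f, 1−f), and kept when MAF > 1 % (strict).

## Linkage disequilibrium

Each resolved haplotype carries one token per panel gene: allele + upstream
label, or the first-class token `absent` (a haplotype can genuinely lack
expression of a gene). Expected count of a combination under random
association: N · Π(marginal token frequencies), plug-in, no continuity
correction; enrichment is observed/expected, reported only for combinations
observed ≥ 2 times, with no significance testing attached (expected = 0
yields an undefined, not infinite, ratio).

## Synthetic repertoire generator

The generator emulates a naive-IgM 5'-RACE cohort: per allele a set of
planted full-length upstream variants (default two at 60:40, differing at
one position drawn 40–90 bases from the V boundary, placed on opposite
chromosomes), ~60-base synthetic V stand-ins, random CDR3 junctions (8–22
aa, every read an independent rearrangement), a J-het genotype
(IGHJ6*02/*03) with 0.5 % J mis-assignment, molecule-level substitution
error (default 0.001/base; `V_errors` counts the V-region hits exactly),
and forward-read decoration with an 8–16-nt barcode, `TAC`, and a 3–15-nt
G-tail. Read 5' extents follow a truncated geometric with P(full
extent) = 0.7 (minimum extent 40), chosen so that the full planted variant
is the inferable consensus with comfortable margin at subgroup sizes down
to ~40 reads, while configurations with P(full) < 0.5 exercise the
50 %-coverage truncation non-trivially in dedicated tests.

Two generator constraints keep trim-level ground truth exact: barcodes are
resampled until the adaptor motif's first occurrence in the decorated
prefix is the true adaptor start, and a read's fragment never begins with G
(a leading biological G is indistinguishable from the tail, so the
recoverable fragment starts at the first non-G base; the truth record
stores exactly that fragment).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: somatic hypermutation lineages, indel sequencing
errors, clonal expansion (every read is an independent rearrangement),
realistic gene-usage and allele-similarity structure, primer or PCR bias,
and quality-score variation (all bases are emitted at a single quality).

## Numerical and degenerate-input choices

All threshold comparisons are inclusive (≥ 30 %, ≥ 50 %, ≥ 80 %) and
evaluated as floating-point fraction-vs-threshold in a single canonical
form. Empty read sets are errors for consensus building; empty post-trim
reads are discarded and counted; variants shorter than the leader length
get a warning annotation instead of a 5'UTR boundary; expression frequency
with zero filtered reads is an error; `N` bases never count as coverage.
Determinism: the generator threads one seeded NumPy generator; consensus,
consolidation and labelling are deterministic by explicit sort orders.

## Known limitations

* Haplotyping is restricted to a single configured anchor J gene; subjects
  heterozygous only at other anchors are treated as non-haplotypable.
* Read-to-variant matching drops reads too short to discriminate sibling
  variants; expression frequencies are therefore lower bounds when sibling
  variants differ only far 5'.
* The consensus walk can emit a sub-30 %-mixture variant only via a split;
  a variant expressed below 30 % of its allele's reads is invisible by
  construction.
* Leader-length annotation trusts the configured per-gene table; it does
  not discover atypical signal-peptide lengths.
* The trimmer removes genuine biological 5'-terminal G-runs along with the
  tail; inferred 5'UTRs can be shorter than the true transcript start.
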