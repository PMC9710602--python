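# Methods

## Design model

An asRNA is defined entirely by its target window. With mRNA coordinate 0
at the first base of the start codon (negative upstream), a window of
length *L* at offset *o* covers mRNA positions [*o*, *o*+*L*). Genomically,
for a plus-strand gene with feature span [start, end) this is
[start+*o*, start+*o*+*L*); for a minus-strand gene it is
[end−*o*−*L*, end−*o*). The asRNA is the reverse complement of the
window's coding-strand (mRNA-sense) sequence; there is no thermodynamic or
secondary-structure scoring — complementarity is the whole model, which is
what makes the probe's behaviour auditable from the output tables alone.

The offset convention — *o* is the mRNA coordinate of the window's 5'-most
base — is the one choice in the anchor arithmetic that was genuinely open.
It is the simplest convention under which the default −8 places a 21-nt
window over −8..+12, covering the tail of a typically positioned
Shine–Dalgarno motif (assumed span −15..−5, exposed as
`design.DEFAULT_SD_SPAN`, not hard-coded into any rule), the start codon
and the early CDS. Under this convention any offset ≥ 0 avoids all
upstream sequence; tools and protocols that anchor on the window centre
will quote different equivalent offsets, so the convention is stated here
and in every docstring that touches it.

Degenerate placements are errors, never silently adjusted: a window
crossing a linear contig boundary raises rather than clamps (a clamped
probe would violate the length contract), and a positive offset whose
window runs past the CDS 3' end is refused because the probe would leave
the transcript it is supposed to silence. On circular contigs windows wrap
modulo the genome length. Compound (joined) CDS locations have no
well-defined start-codon anchor and are skipped with a warning; the gene
appears in the report as undesignable. CDSs are designed for regardless of
whether they begin with a canonical start codon — annotation is taken at
face value.

Coordinates are 0-based half-open everywhere inside the package;
GenBank/EMBL 1-based inclusive coordinates exist only at the parsing and
report-writing boundaries (reported `window_start_1based` = internal start
+ 1, `window_end_1based` = internal end).

## Off-target screen

The screen asks at which loci, on either strand of any contig, the binding
footprint recurs. The unit of evaluation is a *diagonal*: an ungapped
placement of the footprint (strand +1) or its reverse complement
(strand −1) against the forward genome text. On each diagonal the
maximal-scoring contiguous segment under match +1 / mismatch −2 is found
(ties broken longest, then leftmost); `N` never matches anything, which is
also why an all-N query returns nothing. A segment is reported when its
length reaches `min_match_length` and its identity reaches `min_identity`.
Hits are deduplicated by (subject interval, strand) keeping the
highest-identity alignment; a hit overlapping the design window by ≥ 1 bp
on the design strand is the intended site, everything else an off-target,
and off-targets are counted wherever they fall — inside genes or not.

Two routes compute the same definition. `brute_force_scan` evaluates every
diagonal (O(genome × footprint); it is the oracle in the test suite, kept
fast by vectorizing the per-diagonal Kadane scan across all diagonals at
once). `find_matches` evaluates only diagonals nominated by an exact seed
word shared between footprint and genome. The requested `seed_word_size`
(default 11) is capped at the lossless filtration bound: a reportable
alignment of length *l* with *e* mismatches must contain an exact run of
at least ⌈(*l*−*e*)/(*e*+1)⌉ nt, and minimizing this over the admissible
lengths gives the longest seed that can never miss a hit (3 nt at the
default 80%/15-nt thresholds, 21 nt at 100%/21). The cap trades filtration
power for exactness: with permissive thresholds the seeded matcher
degenerates gracefully toward the exhaustive scan instead of silently
dropping weak hits, and the two routes agree bit-for-bit by construction.
Gapped alignment is deliberately out of scope — indels in a 21-nt
RNA–RNA duplex are marginal and would buy ambiguity, not sensitivity.

The external backend exports the genome and footprints to FASTA and runs
`blastn -task blastn-short` with the user's e-value and identity
thresholds, parsing standard 12-column tabular output. The footprint (not
the asRNA strand) is the query so subject-strand semantics match the
builtin matcher. Known differences from the builtin: BLAST supplies
e-values (the builtin reports none, since Karlin–Altschul calibration is
not meaningful for its raw score), its database is linear (origin-spanning
hits on circular contigs are missed), and its `score` column is
reconstructed as matches − 2·mismatches from the tabular fields so the two
backends are comparable.

## Workflow

Round 1 designs every selected gene at the configured offset and screens
the batch. Genes with ≥ 1 off-target are redesigned once at
offset + `redesign_step` (default: the asRNA length, making the two
windows disjoint while staying near the translation-initiation region —
stepping downstream rather than upstream keeps the probe inside the
transcript) and screened again. The two-round cap is structural, not a
loop bound: there is no code path to a third screen. Statuses partition
the targets: `clean_round1`, `clean_round2`, `flagged` (still dirty after
round 2; ships the round-2 design plus all evidence), `undesignable`
(window construction failed in round 1, with a machine-readable reason).
A gene flagged in round 1 whose round-2 window cannot be placed keeps the
round-1 design, status `flagged`, with the failure noted. Per-gene
failures never abort a batch.

Output is two CSV tables (designs, hits; RFC-4180, UTF-8, fixed documented
headers) plus a JSON provenance sidecar; `xlsx` packs the same two tables
into one workbook. The timestamp lives only in the sidecar and can be
suppressed, making reruns byte-identical — the tables themselves never
contain volatile fields.

## Synthetic genomes

The generator emulates what the design and screening logic actually
consumes: multi-gene contigs (linear or circular) with ATG-prefixed random
genes at a configurable GC content, random intergenic spacers, both
strands, and optionally planted duplicate loci. `sd_start_region`
duplicates copy mRNA span [−20, +13) — Shine–Dalgarno region through the
end of the default round-1 window, so round 1 is trapped and round 2
escapes; `whole_gene_with_flanks` copies the gene ± 30 nt, trapping both
rounds. It does not emulate codon usage, operons, promoters, overlapping
genes or expression, so passing tests demonstrate the correctness of the
design/screen/redesign machinery, not knockdown efficacy on real
transcriptomes.

Clean screens are guaranteed, not just likely: a candidate genome is
rejection-sampled until (a) no 15-mer occurs twice (canonical, i.e.
counting reverse complements) outside planted spans, and (b) every default
round-1/round-2 window, screened with the brute-force oracle at default
thresholds, hits nothing beyond its own site and the planted duplicates.
Check (b) matters because an 80%-identity screen can be tripped by chance
near-matches that share no long exact word. It is also why large fixtures
cannot be guaranteed clean: the expected number of chance near-matches
grows with genome size and reaches O(10) per design set by ~10 kb, so
design-only fixtures (e.g. the 50-gene genome used to exercise the
reverse-complement contract, which is never screened) set
`screen_guard=False`. Sampling is deterministic: attempt *k* for seed *s*
uses the seed sequence (*s*, *k*), so a fixed spec always yields a
byte-identical genome and GenBank file.

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic genomes of
1–8 kb (6–50 genes; 20 duplicated genomes of ~4.4 kb for the
matcher-vs-oracle comparison), sizes at which the exhaustive oracle is
cheap and the clean-screen guarantee is samplable; the library itself is
routinely usable on megabase bacterial genomes with the builtin matcher,
where per-design cost is O(genome) with a small vectorized constant.
Identity thresholds are compared as integer match counts against
`min_identity × length` with a 1e-9 guard, so no hit can flip on float
rounding. Determinism is end-to-end: same inputs and parameters give
identical reports, and fixed-seed fixtures give identical bytes.

## Known limitations

- No RNA–RNA hybridization energetics or accessibility modelling; ranking
  within the reported library is out of scope.
- Off-targets are screened against the genome, not an expressed-transcript
  set, so hits in never-transcribed regions are reported (conservative).
- The external BLAST backend treats contigs as linear.
- Compound/joined CDSs are not designed for.
- Scaffold/vector assembly around the asRNA sequence is out of scope; the
  output is the antisense region itself.
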