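# asrnadesign

Genome-wide design of bacterial antisense RNAs (asRNAs) with built-in
off-target screening.

Antisense pairing between a short RNA and a target mRNA down-regulates the
gene post-transcriptionally, which makes systematically designed asRNA
libraries an attractive complement to knockout collections for bacterial
functional genomics: knockdowns are inducible, work on essential genes, and
move easily between genetic backgrounds. `asrnadesign` takes an annotated
genome (GenBank or EMBL) and, for every coding sequence — or an optional
subset listed by locus tag or gene name — produces one asRNA, screens it
against the whole genome for off-target binding sites, redesigns flagged
probes exactly once at a new offset, and writes the final library with all
screening evidence.

## The design rule

Let mRNA coordinate 0 be the first base of the start codon, negative
coordinates upstream. An asRNA of length *L* at offset *o* is the perfect
reverse complement of the mRNA window [*o*, *o*+*L*). The defaults, *L* = 21
and *o* = −8, place the window over positions −8..+12: the tail of the
Shine–Dalgarno region, the start codon and the first codons — the region
where antisense occlusion of translation initiation is most effective. Users
who want to avoid the SD sequence entirely can choose a positive offset.

## Off-target screening

A probe's binding footprint is searched against both strands of every
contig with an ungapped seed-and-extend matcher (match +1, mismatch −2,
maximal-scoring trim). A locus is reported when the best alignment reaches
`min_match_length` (default 15 nt) at `min_identity` (default 80%); the
intended design site is recognised by overlap with the design window and
everything else counts as an off-target. The seed length is capped at the
lossless filtration bound implied by the thresholds, so the seeded matcher
provably returns the same hit set as an exhaustive scan. A local NCBI
BLAST+ install can be used instead (`--backend blast`) when e-value based
screening is preferred.

A gene whose round-1 screen finds off-targets is redesigned once,
`redesign_step` nt (default: the asRNA length) further downstream, and
screened again. There is never a third round — for recent high-identity
gene duplicates the loop would not terminate and would walk the probe out
of the gene — so genes still dirty after round 2 ship `flagged`, carrying
their round-2 design and the full hit table for the user to judge.

## Worked example

Generate a small synthetic genome in which gene 1's Shine–Dalgarno/start
region is duplicated at a second locus, then design a library:

```bash
python -c "
from asrnadesign.synthetic import SyntheticGenomeSpec, make_genome
make_genome(SyntheticGenomeSpec(n_genes=6, seed=11,
                                duplicate_pairs=[(0, 'sd_start_region')]),
            path='demo_genome.gb')"
asrna-design --genome demo_genome.gb --out demo --no-timestamp
```

prints

```
7 genes: clean_round1=5, clean_round2=2
wrote demo_designs.csv
wrote demo_hits.csv
wrote demo_run_info.json
```

Five genes were clean on the first pass; the duplicated pair (the source
gene and its copy) each picked up one off-target in round 1 and came out
clean after the single redesign at offset −8 + 21 = +13. The designs table
records, per gene, the final window (1-based inclusive coordinates), the
sense sequence and its reverse-complement asRNA:

```
locus_tag,gene_name,product,strand,round,offset,window_start_1based,window_end_1based,target_sense_seq,asrna_seq,status,offtarget_count,undesignable_reason
SYN_0001,syn1,synthetic protein,-,2,13,147,167,ATTCTCGGGCATCCTGTCGAA,TTCGACAGGATGCCCGAGAAT,clean_round2,0,
SYN_0002,syn2,synthetic protein,+,1,-8,233,253,AAACGGAAATGCGCCTAATCA,TGATTAGGCGCATTTCCGTTT,clean_round1,0,
```

and the hits table holds every alignment from both screening rounds, with
the intended design site flagged:

```
locus_tag,round,subject_contig,subject_start_1based,subject_end_1based,subject_strand,aligned_length,identity,score,evalue,is_intended
SYN_0001,1,SYNCONTIG1,168,188,-,21,100.0,21,,True
SYN_0001,1,SYNCONTIG1,1248,1268,-,21,100.0,21,,False
```

`--out-format xlsx` writes the same two tables as one workbook. All flags
can also be given through `--config file` (`key=value`, one per line);
explicit flags win.

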