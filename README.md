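# kmotif

Regulatory-motif analysis for cluster K mycobacteriophage genomes, and the
design arithmetic for converting a temperate phage into a lytic one by
repressor-gene deletion.

Cluster K mycobacteriophages — candidates for therapy of *Mycobacterium
tuberculosis* and nontuberculous mycobacterial infections — carry two short
regulatory elements near their gene starts:

- **SAS** (Start-Associated Sequence): occurrences of the 13-nt consensus
  `GGGATAGGAGCCC` within a Hamming-distance budget *m* (default ≤ 2
  mismatches), typically found just upstream of translation starts;
- **ESAS** (Extended SAS): pairs of imperfect 17-nt inverted repeats —
  a left repeat *L*, a variable spacer, and a right repeat *R* with
  `Hamming(L, revcomp(R)) ≤ k` — whose right repeat often ends exactly on
  the first base of a downstream start codon.

`kmotif` provides exhaustive, oracle-verified scanners for both elements,
gene-start classification (upstream / intragenic / distal within a
configurable upstream window), per-position repeat composition profiles,
cross-subcluster comparative statistics (mean motifs per genome, pooled
exact-match percentage, mismatch histograms), and the BRED
(Bacteriophage Recombineering of Electroporated DNA) substrate designer:
a 50-nt base oligo joining 25-nt deletion flanks, two nested pairs of 58-nt
extender primers, and the 200-nt junction amplicon, plus in-silico mutant
construction with coordinate lift-over and codon-level SNP effect
annotation. A seeded synthetic-genome generator plants elements at exact
mismatch counts so every scanner is testable without downloads.

## Worked example

Generate a 20-kb synthetic phage with two planted SAS motifs (one exact, one
with 2 mismatches) and one planted ESAS whose right repeat ends on a gene
start:

```bash
$ kmotif simulate --spec spec.json --seed 11 --out-prefix demo
fixture demo_phage: 20000 bp -> demo.*

$ kmotif stats --genome demo.fasta --gff demo.gff3
genome_id   length_bp  gc_percent  orf_count  coding_bp  coding_fraction_percent
demo_phage  20000      67.08       18         16902      84.5

$ kmotif scan-sas --genome demo.fasta --gff demo.gff3 --out sas.tsv
4 SAS hits -> sas.tsv
```

`sas.tsv` (header comments omitted):

```text
genome_id   start  end    strand  mismatches  score  observed       category    associated_gene  distance_to_start
demo_phage  4077   4089   -       2           11     GGGCCAGGAGCCC  intragenic  syn_00004
demo_phage  4573   4585   +       0           13     GGGATAGGAGCCC  upstream    syn_00005        21
demo_phage  10004  10016  +       2           11     ACGATAGGAGCCC  upstream    syn_00010        35
demo_phage  17845  17857  +       2           11     GGGTCAGGAGCCC  intragenic  syn_00017
```

Both planted motifs are recovered at their planted coordinates, mismatch
counts and upstream distances (21 and 35 nt); the two extra rows are
background windows that happen to sit within the 2-mismatch budget — the
expected false-positive rate is `2(L−12)·742/4^13` per genome, where 742 is
the number of 13-mers within 2 mismatches of the consensus.

```bash
$ kmotif scan-esas --genome demo.fasta --gff demo.gff3 --sas-hits sas.tsv --max-pair-mm 1 --out esas.tsv
2 ESAS hits -> esas.tsv
```

```text
left_start  left_end  right_start  right_end  spacer_len  repeat_len  pair_mismatches  start_codon_coincident
13281       13297     13304        13320      6           17          1                False
13282       13298     13303        13319      4           17          1                True
```

The planted element (left start 13282, spacer 4, 1 mismatch) is flagged
`start_codon_coincident` because its right repeat ends on the first base of
`syn_00013`'s start codon; the first row is the same physical stem shifted
outward by one base (shifted variants with distinct left starts are reported,
not merged). Finally, design the deletion that removes that gene except its
first 45 bp:

```bash
$ kmotif design-deletion --genome demo.fasta --gff demo.gff3 --gene syn_00013 --retain-5p 45 --out design.json
deletion [13364,14257] (894 bp) -> design.json
```

`design.json` holds the 50-nt base oligo joining the two 25-nt flanks, the
200-nt junction amplicon, and the four 58-nt extender primers with the
extension bookkeeping (`round1_extension_per_side: 38`,
`round2_extension_per_side: 37`, overlaps 20/21 nt — the 75 nt per side do
not split evenly, so the rounds are unequal).

The same operations are available as a library (`kmotif.scan_consensus`,
`kmotif.scan_inverted_repeats`, `kmotif.classify_hits`,
`kmotif.design_deletion_substrate`, …); see `docs/methods.md` for the model
definitions, parameter semantics and limitations.

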