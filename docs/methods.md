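# Methods

`kmotif` analyses the short regulatory elements characteristic of cluster K
mycobacteriophage genomes and performs the interval arithmetic behind BRED
(Bacteriophage Recombineering of Electroporated DNA) deletion engineering.
This note records the models, the parameters that matter, the numerical
conventions, and the limits of what the synthetic fixtures can show.

## SAS scanning

A Start-Associated Sequence (SAS) is modelled as an occurrence of a fixed
13-nt consensus, `GGGATAGGAGCCC`, within a Hamming-distance budget. The
scanner is exhaustive: every window on each requested strand is compared to
the consensus (to its reverse complement for − strand hits), so the hit set
at budget *m* is by construction a superset of the set at *m* − 1, and
scanning a reverse-complemented genome reproduces the same hits under the
coordinate map `pos ↦ L − end + 1` with strands swapped. A quasi-palindromic
window can hit on both strands; both are reported and counted. Bases outside
{A,C,G,T} (N and IUPAC ambiguity codes) never match anything, including
themselves — conservative and deterministic.

Parameters:

| parameter | default | meaning |
|---|---|---|
| `consensus` | `GGGATAGGAGCCC` | the motif searched for (13 nt) |
| `max_mismatches` | 2 | Hamming budget; 3 for the extended "divergent forms" search |
| `strands` | both | − strand hits are read in motif orientation |
| `upstream_window_nt` | 100 | window before a translation start used for classification |

Classification is three-way and exhaustive (the categories partition the hit
list): a hit overlapping any coding interval on either strand is
*intragenic* (this includes hits overlapping a start codon); otherwise a hit
lying wholly within the `upstream_window_nt` nucleotides before some gene's
translation start, on that gene's strand, is *upstream* of the nearest such
gene (ties by smaller gap, then lexicographic locus tag); everything else is
*distal*. The reported distance is the nucleotide gap between the motif's
near edge and the start codon (0 when adjacent). 100 nt is a deliberate
default: it covers typical phage 5′ leaders while excluding mid-intergenic
noise, and it is the single knob shared with the extended ≤3-mismatch
search. It is a calibration parameter, not a published constant.

## ESAS detection

An Extended SAS (ESAS) is a pair of imperfect inverted repeats: a left
repeat of width 17, a spacer, and a right repeat of the same width, scored
by `Hamming(left, revcomp(right))`. Detection enumerates every
(left_start, spacer) combination with the spacer in a configured range —
vectorised as one byte-comparison pass per (spacer, offset) pair — and keeps
pairs within the mismatch budget. Candidates sharing a left start are
deduplicated to the best (fewest mismatches, then shortest spacer); shifted
variants of the same physical stem with *different* left starts are all
reported, since the structure definition gives no canonical anchor.

The repeat width (17) is the one published constant; the mismatch budget
(default 3) and spacer range (default 0–50 nt) quantify "imperfect" and
"variable" and are exposed, documented knobs. SAS proximity (default 50 nt)
and start-codon coincidence (`right_end` equal to the first base of a +
strand gene's start codon; mirrored for − strand genes) are *annotations*
added after detection, never filters — the published counts themselves show
elements far from any SAS.

Per-position repeat composition (`repeat_profile`) tallies each repeat as
its literal genomic substring, positions 1…17 left to right, so "position
14 of the right repeat" means the 14th base of the right repeat's + strand
text. Column sums equal the number of sequences profiled.

## Comparative statistics

Per-genome scan results are pooled by subcluster. The exact-match percentage
is pooled by default — 100 × (hits with 0 mismatches) / (all hits) over the
subcluster's genomes — with a per-genome-mean alternative behind a flag;
pooling is scale-free (duplicating every genome changes nothing) and defined
whenever the subcluster has at least one hit. Genomes with zero hits dilute
the per-genome mean but contribute nothing to the exact-match denominator;
a subcluster with no hits reports the percentage as missing, never 0. The
"top 5" figure column is realised as the per-genome scores of the five
best-scoring hits (score = consensus length − mismatches; ties broken by
leftmost start, then + strand first).

## BRED deletion design

For a gene deletion retaining an initial 5′ stub, the deletion interval is
`[gene_start + retained, gene_end]` on a + strand gene (mirrored on −). The
substrate is assembled positionally:

- **base oligo** (default 50 nt): the last 25 nt before the deletion joined
  to the first 25 nt after it;
- **amplicon** (default 200 nt): the junction-joined flanks extended
  symmetrically, so the base oligo is its exact centre;
- **extender primers** (two nested pairs, default 58 nt): each PCR round
  extends both ends by `primer_len − overlap`. The two rounds must grow
  50 → 200, i.e. 75 nt per side; 75 is odd, so the rounds are unequal
  (38 + 37 nt per side, overlaps 20/21 nt) and the division is recorded in
  the design report. A round whose annealing overlap would drop below 10 nt
  is rejected as a design error.

Primer choice is purely positional; no melting-temperature or secondary-
structure screening is attempted (the engineering protocol specifies
lengths, not thermodynamics). Invariants checked by the tests: the base
oligo and every primer occur exactly once in the amplicon (or its reverse
complement), the amplicon is a substring of the deletion-spliced wild type,
and excision followed by re-insertion restores the wild-type sequence.

Mutant construction applies user-supplied SNPs (validated against the
reference base) before excising the deletion, and emits a wild-type→mutant
lift-over that is monotone and bijective outside the deleted interval.
SNP effects are annotated by translating the affected codon before and after
the substitution (standard genetic code, strand-aware); changes are reported
three-letter (`Thr463Ile`), stop codons as `Stop`, and identical residues as
`synonymous`. A SNP inside overlapping coding regions yields one effect per
region.

## Synthetic fixtures

The generator emulates the shape of a cluster K genome: 57,978 bp, 67% GC,
94 CDS laid out head-to-tail with a fixed intergenic gap (default 35 nt,
giving ~93.4% coding), ~97% of genes on the forward strand, start/stop
codons written at gene boundaries. The background is i.i.d. with a GC knob;
because the forced start/stop codons are AT-rich, the background draw is
GC-compensated so the whole-genome expectation equals the target. Planted
SAS copies carry *exactly* the requested Hamming distance, and a
post-generation guard redraws the immediate background if an accidental
equally-good match arises next to a plant, so recall assertions are exact
rather than probabilistic. Planted ESAS elements are `L + spacer +
revcomp(L)` with the requested number of substitutions in the right repeat;
optional variants snap the right-repeat end to a gene start or add an exact
SAS 10 nt upstream of the left repeat.

What the fixtures do **not** emulate: dinucleotide/codon structure, operon
organisation, the uneven intergenic-gap distribution of real genomes, the
positional clustering of regulatory elements in the genome's right arm, and
phylogenetic correlation between genomes. Passing fixture tests therefore
demonstrates the scanners' correctness and calibration *mechanics*, not that
the default thresholds reproduce counts on real records — that is what the
reproduction workflow (`kmotif.reproduce` + `scripts/reproduce_published.py`)
checks when the GenBank records are available.

A sanity bound for false positives: a random genome of length *L* yields
about `2 (L − 12) · N(13, 2) / 4^13` background SAS hits, with
`N(13, 2) = 742` the Hamming-neighbourhood size; the test suite checks
observed background counts against a 4σ binomial band.

## Numerical and format conventions

- Coordinates are 1-based inclusive everywhere internally and in TSV/GFF3;
  only BED export is 0-based half-open. Conversions are exact integer maps.
- GC% is computed over non-N bases; coding bp sums CDS lengths per feature
  ("collectively spanning" — overlaps counted per feature, not unioned);
  rounding happens only at presentation time.
- CDS features define ORFs; gene features are used (with a logged warning)
  only when a record has no CDS. Compound (join) locations are flattened to
  their outermost span with a warning.
- Problem sizes in the test and acceptance runs: oracle-equivalence checks
  use 2–5 kb random sequences (exhaustive enumeration is quadratic in the
  spacer range); recall is measured over five 25-kb fixtures with 35 planted
  elements; genome statistics use the full 57,978-bp default fixture.

## Known limitations

- The published ESAS thresholds (mismatch budget, spacer bounds) are not
  printed in the source literature; the defaults here are field-plausible
  choices and may need recalibration against the deposited records before
  quantitative comparison with published counts.
- The scanner reports every window within budget; no merging of overlapping
  shifted inverted-repeat variants is attempted, which inflates raw ESAS
  totals relative to a per-element count on repeat-dense sequence.
- Only single-contig, linear-coordinate genomes are handled; join locations
  spanning a circular origin are flattened, not split.
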