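"""BRED deletion-substrate design and in-silico mutant construction.

The recombineering substrate for a gene deletion is built from a short base
oligo joining the two deletion flanks (default 50 nt: 25 + 25), which two
successive PCR extension rounds with nested primer pairs (default 58 nt)
grow into the final double-stranded amplicon (default 200 nt) centred on the
deletion junction. Primer design here is purely positional — nested
substring extraction from the target amplicon — with no melting-temperature
or secondary-structure screening.

The module also applies a designed deletion (plus any engineered or
spontaneous SNPs) to the wild-type genome, emits a wild-type→mutant
coordinate lift-over, and annotates SNP effects at codon level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from kmotif.errors import DesignError, ValidationError
from kmotif.genome_io import GeneFeature, GenomeRecord
from kmotif.seqops import revcomp


@dataclass(frozen=True)
class DeletionSpec:
    """What to delete: a gene (by locus_tag) minus a retained 5' stub, or an
    explicit 1-based inclusive interval."""

    genome_id: str
    target_gene: Optional[str] = None
    interval: Optional[tuple[int, int]] = None
    retained_5prime_bp: int = 0

    def __post_init__(self) -> None:
        if (self.target_gene is None) == (self.interval is None):
            raise ValidationError("specify exactly one of target_gene / interval")
        if self.retained_5prime_bp < 0:
            raise ValidationError("retained_5prime_bp must be >= 0")


@dataclass(frozen=True)
class SubstrateDesign:
    base_oligo: str
    extender_primers: dict[str, str]  # f1, r1, f2, r2
    amplicon: str
    deletion_interval: tuple[int, int]  # 1-based inclusive; end < start ⇒ empty
    junction_offset: int  # nt of amplicon preceding the junction
    report: dict = field(default_factory=dict)

    @property
    def deletion_length(self) -> int:
        return max(0, self.deletion_interval[1] - self.deletion_interval[0] + 1)


@dataclass(frozen=True)
class VariantEffect:
    position: int
    ref: str
    alt: str
    region: str  # intergenic | CDS
    gene: Optional[str] = None
    codon_index: Optional[int] = None
    aa_change: Optional[str] = None  # e.g. Thr463Ile, or "synonymous"


@dataclass(frozen=True)
class LiftOver:
    """Wild-type → mutant coordinate map after one deletion.

    Monotone and bijective outside the deleted interval; deleted positions
    map to None.
    """

    deletion_interval: tuple[int, int]

    def wild_to_mutant(self, pos: int) -> Optional[int]:
        ds, de = self.deletion_interval
        dlen = max(0, de - ds + 1)
        if dlen and ds <= pos <= de:
            return None
        return pos if pos < ds else pos - dlen

    def mutant_to_wild(self, pos: int) -> int:
        ds, de = self.deletion_interval
        dlen = max(0, de - ds + 1)
        return pos if pos < ds else pos + dlen


def resolve_deletion_interval(
    features: Sequence[GeneFeature], spec: DeletionSpec
) -> tuple[int, int]:
    """Deletion interval for a gene-targeted spec: the gene span minus a
    retained 5' stub ([start + retained, end] on +, mirrored on −)."""
    if spec.interval is not None:
        return spec.interval
    matches = [f for f in features if f.locus_tag == spec.target_gene]
    if not matches:
        raise ValidationError(f"gene {spec.target_gene!r} not found in annotation")
    gene = matches[0]
    if spec.retained_5prime_bp >= gene.length:
        raise ValidationError(
            f"retained_5prime_bp {spec.retained_5prime_bp} >= gene length {gene.length}"
        )
    if gene.strand == "+":
        return gene.start + spec.retained_5prime_bp, gene.end
    return gene.start, gene.end - spec.retained_5prime_bp


def design_deletion_substrate(
    genome: GenomeRecord,
    features: Sequence[GeneFeature],
    spec: DeletionSpec,
    base_len: int = 50,
    primer_len: int = 58,
    amplicon_len: int = 200,
) -> SubstrateDesign:
    """Design the base oligo, nested extender primers and final amplicon.

    The amplicon is the junction-joined flanking sequence extended
    symmetrically to ``amplicon_len``; the base oligo sits at its centre.
    Two extension rounds grow base_len → amplicon_len; per-round extension
    lengths are computed to land exactly on amplicon_len (unequal rounds
    when the total does not split evenly) and recorded in the report.
    """
    if base_len % 2 or amplicon_len % 2:
        raise DesignError("base_len and amplicon_len must be even")
    if amplicon_len <= base_len:
        raise DesignError("amplicon_len must exceed base_len")
    ds, de = resolve_deletion_interval(features, spec)
    del_len = de - ds + 1
    if del_len < 0:
        raise ValidationError(f"invalid deletion interval [{ds},{de}]")
    if del_len == 0:
        warnings.warn("zero-length deletion: designing an identity junction", stacklevel=2)
    half = amplicon_len // 2
    if ds - 1 < half or genome.length_bp - de < half:
        raise DesignError(
            f"deletion [{ds},{de}] needs {half} nt of flank on each side"
        )
    left_flank = genome.sequence[ds - 1 - half : ds - 1]
    right_flank = genome.sequence[de : de + half]
    amplicon = left_flank + right_flank
    b0 = half - base_len // 2  # base oligo start within amplicon (0-based)
    base_oligo = amplicon[b0 : b0 + base_len]

    # Two extension rounds per side: e1 + e2 = (amplicon_len - base_len) / 2.
    total_ext = (amplicon_len - base_len) // 2
    e1 = (total_ext + 1) // 2
    e2 = total_ext - e1
    o1, o2 = primer_len - e1, primer_len - e2  # primer/template overlaps
    if min(o1, o2) < 10:
        raise DesignError(
            f"primer_len {primer_len} leaves a {min(o1, o2)} nt annealing "
            f"overlap; too short to bridge a round"
        )
    # Round-1 product spans amplicon[b0-e1 : b0+base_len+e1]; round 2 spans all.
    f1 = amplicon[b0 - e1 : b0 - e1 + primer_len]
    r1 = revcomp(amplicon[b0 + base_len + e1 - primer_len : b0 + base_len + e1])
    f2 = amplicon[0:primer_len]
    r2 = revcomp(amplicon[amplicon_len - primer_len : amplicon_len])
    return SubstrateDesign(
        base_oligo=base_oligo,
        extender_primers={"f1": f1, "r1": r1, "f2": f2, "r2": r2},
        amplicon=amplicon,
        deletion_interval=(ds, de),
        junction_offset=half,
        report={
            "genome_id": genome.genome_id,
            "target_gene": spec.target_gene,
            "deletion_interval": [ds, de],
            "deletion_length": del_len,
            "base_len": base_len,
            "primer_len": primer_len,
            "amplicon_len": amplicon_len,
            "round1_extension_per_side": e1,
            "round2_extension_per_side": e2,
            "round1_overlap": o1,
            "round2_overlap": o2,
        },
    )


def build_mutant_genome(
    genome: GenomeRecord,
    deletion_interval: tuple[int, int],
    snps: Sequence[tuple[int, str, str]] = (),
    mutant_id: Optional[str] = None,
) -> tuple[GenomeRecord, LiftOver]:
    """Apply SNPs (wild-type coordinates, outside the deletion) then excise
    the deletion interval. Returns the engineered genome and the wild-type →
    mutant lift-over."""
    ds, de = deletion_interval
    dlen = max(0, de - ds + 1)
    seq = list(genome.sequence)
    for pos, ref, alt in snps:
        if dlen and ds <= pos <= de:
            raise ValidationError(f"SNP position {pos} lies inside the deletion")
        if not 1 <= pos <= genome.length_bp:
            raise ValidationError(f"SNP position {pos} outside genome")
        if seq[pos - 1] != ref.upper():
            raise ValidationError(
                f"reference mismatch at {pos}: genome has {seq[pos - 1]}, "
                f"expected {ref.upper()}"
            )
        seq[pos - 1] = alt.upper()
    if dlen:
        del seq[ds - 1 : de]
    mutant = GenomeRecord(
        genome_id=mutant_id or f"{genome.genome_id}_mut",
        sequence="".join(seq),
        topology=genome.topology,
    )
    return mutant, LiftOver(deletion_interval=(ds, de))


def annotate_snp_effect(
    genome: GenomeRecord,
    features: Sequence[GeneFeature],
    snp: tuple[int, str, str],
) -> list[VariantEffect]:
    """Effect(s) of one SNP: a codon-level amino-acid change for each CDS it
    falls in (strand-aware, standard genetic code), or a single intergenic
    record. Amino-acid changes are reported three-letter, e.g. Thr463Ile;
    identical residues report "synonymous"."""
    pos, ref, alt = snp
    ref, alt = ref.upper(), alt.upper()
    if not 1 <= pos <= genome.length_bp:
        raise ValidationError(f"SNP position {pos} outside genome")
    if genome.sequence[pos - 1] != ref:
        raise ValidationError(
            f"reference mismatch at {pos}: genome has {genome.sequence[pos - 1]}, "
            f"expected {ref}"
        )
    hosts = [
        f
        for f in features
        if f.feature_kind == "CDS" and f.start <= pos <= f.end
    ]
    if not hosts:
        return [VariantEffect(position=pos, ref=ref, alt=alt, region="intergenic")]
    effects = []
    for cds in hosts:
        if cds.strand == "+":
            offset = pos - cds.start  # 0-based within CDS
            cds_seq = genome.sequence[cds.start - 1 : cds.end]
            mut_base = alt
        else:
            offset = cds.end - pos
            cds_seq = revcomp(genome.sequence[cds.start - 1 : cds.end])
            mut_base = revcomp(alt)
        codon_index = offset // 3 + 1
        cstart = (codon_index - 1) * 3
        codon = cds_seq[cstart : cstart + 3]
        in_codon = offset % 3
        mut_codon = codon[:in_codon] + mut_base + codon[in_codon + 1 :]
        aa_wt = str(Seq(codon).translate())
        aa_mut = str(Seq(mut_codon).translate())
        if aa_wt == aa_mut:
            change = "synonymous"
        else:
            wt3 = "Stop" if aa_wt == "*" else seq3(aa_wt)
            mut3 = "Stop" if aa_mut == "*" else seq3(aa_mut)
            change = f"{wt3}{codon_index}{mut3}"
        effects.append(
            VariantEffect(
                position=pos, ref=ref, alt=alt, region="CDS",
                gene=cds.locus_tag, codon_index=codon_index, aa_change=change,
            )
        )
    return effects
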