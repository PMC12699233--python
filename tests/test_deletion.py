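import pytest

from kmotif import (
    DeletionSpec,
    GeneFeature,
    GenomeRecord,
    annotate_snp_effect,
    build_mutant_genome,
    design_deletion_substrate,
)
from kmotif.deletion import resolve_deletion_interval
from kmotif.errors import DesignError, ValidationError
from kmotif.seqops import revcomp
from tests.conftest import random_genome

# Study-shaped scenario: a ~58 kb genome whose repressor gene occupies
# [35678, 36037]; the deletion retains the first 45 bp of the gene.
GENE_START, GENE_END, RETAIN = 35_678, 36_037, 45


@pytest.fixture(scope="module")
def repressor_case():
    genome = random_genome(57_978, seed=42, gc=0.67, genome_id="wt")
    features = [GeneFeature("yp_00047", GENE_START, GENE_END, "+", "CDS", "repressor")]
    spec = DeletionSpec(genome_id="wt", target_gene="yp_00047", retained_5prime_bp=RETAIN)
    return genome, features, spec


class TestDesign:
    def test_repressor_deletion_arithmetic(self, repressor_case):
        genome, features, spec = repressor_case
        design = design_deletion_substrate(genome, features, spec)
        assert design.deletion_interval == (GENE_START + RETAIN, GENE_END)
        assert design.deletion_length == 315
        assert len(design.base_oligo) == 50
        assert len(design.amplicon) == 200
        assert all(len(p) == 58 for p in design.extender_primers.values())

    def test_base_oligo_joins_flanks_across_deletion(self, repressor_case):
        genome, features, spec = repressor_case
        design = design_deletion_substrate(genome, features, spec)
        ds, de = design.deletion_interval
        left = genome.sequence[ds - 26 : ds - 1]
        right = genome.sequence[de : de + 25]
        assert design.base_oligo == left + right

    def test_base_oligo_and_primers_unique_in_amplicon(self, repressor_case):
        genome, features, spec = repressor_case
        d = design_deletion_substrate(genome, features, spec)
        amp_rc = revcomp(d.amplicon)
        assert d.amplicon.count(d.base_oligo) == 1
        for name, p in d.extender_primers.items():
            fwd, rev = d.amplicon.count(p), amp_rc.count(p)
            assert fwd + rev == 1, name

    def test_extension_rounds_land_exactly_on_amplicon(self, repressor_case):
        genome, features, spec = repressor_case
        d = design_deletion_substrate(genome, features, spec)
        r = d.report
        assert r["round1_extension_per_side"] + r["round2_extension_per_side"] == 75
        # round-1 product = f1 ... revcomp(r1); round 2 = f2 ... revcomp(r2)
        assert d.amplicon.startswith(d.extender_primers["f2"])
        assert d.amplicon.endswith(revcomp(d.extender_primers["r2"]))

    def test_amplicon_spans_junction(self, repressor_case):
        genome, features, spec = repressor_case
        d = design_deletion_substrate(genome, features, spec)
        ds, de = d.deletion_interval
        spliced = genome.sequence[: ds - 1] + genome.sequence[de:]
        assert d.base_oligo in spliced
        assert d.amplicon in spliced

    def test_single_base_deletion_limit_case(self):
        genome = random_genome(2_000, seed=43)
        gene = GeneFeature("g", 500, 799, "+")
        spec = DeletionSpec("wt", target_gene="g", retained_5prime_bp=299)
        d = design_deletion_substrate(genome, [gene], spec)
        assert d.deletion_length == 1
        mutant, _ = build_mutant_genome(genome, d.deletion_interval)
        assert mutant.length_bp == genome.length_bp - 1

    def test_zero_length_deletion_gives_contiguous_amplicon(self):
        genome = random_genome(2_000, seed=44)
        spec = DeletionSpec("wt", interval=(900, 899))
        with pytest.warns(UserWarning, match="zero-length"):
            d = design_deletion_substrate(genome, [], spec)
        assert d.amplicon == genome.sequence[799:999]
        assert d.amplicon[75:125] == d.base_oligo

    def test_edge_deletion_rejected(self):
        genome = random_genome(2_000, seed=45)
        spec = DeletionSpec("wt", interval=(50, 400))
        with pytest.raises(DesignError):
            design_deletion_substrate(genome, [], spec)

    def test_primer_too_short_rejected(self, repressor_case):
        genome, features, spec = repressor_case
        with pytest.raises(DesignError):
            design_deletion_substrate(genome, features, spec, primer_len=40)

    def test_minus_strand_gene_retains_its_5prime(self):
        genome = random_genome(2_000, seed=46)
        gene = GeneFeature("g", 500, 799, "-")
        spec = DeletionSpec("wt", target_gene="g", retained_5prime_bp=45)
        assert resolve_deletion_interval([gene], spec) == (500, 799 - 45)

    def test_retain_whole_gene_rejected(self):
        gene = GeneFeature("g", 500, 799, "+")
        spec = DeletionSpec("wt", target_gene="g", retained_5prime_bp=300)
        with pytest.raises(ValidationError):
            resolve_deletion_interval([gene], spec)


class TestMutantGenome:
    def test_deletion_shortens_by_length(self, repressor_case):
        genome, features, spec = repressor_case
        d = design_deletion_substrate(genome, features, spec)
        mutant, lift = build_mutant_genome(genome, d.deletion_interval)
        assert mutant.length_bp == 57_978 - 315
        ds, de = d.deletion_interval
        assert mutant.sequence == genome.sequence[: ds - 1] + genome.sequence[de:]

    def test_empty_deletion_with_one_snp(self):
        genome = random_genome(1_000, seed=47)
        pos = 321
        ref = genome.sequence[pos - 1]
        alt = "A" if ref != "A" else "C"
        mutant, _ = build_mutant_genome(genome, (500, 499), [(pos, ref, alt)])
        assert mutant.length_bp == genome.length_bp
        diffs = [i for i, (a, b) in enumerate(zip(genome.sequence, mutant.sequence)) if a != b]
        assert diffs == [pos - 1]

    def test_apply_then_revert_restores_wild_type(self):
        genome = random_genome(1_000, seed=48)
        ds, de = 400, 449
        pos = 100
        ref = genome.sequence[pos - 1]
        alt = "G" if ref != "G" else "T"
        mutant, lift = build_mutant_genome(genome, (ds, de), [(pos, ref, alt)])
        # revert: re-insert the deleted segment and flip the SNP back
        mpos = lift.wild_to_mutant(pos)
        restored = (
            mutant.sequence[: ds - 1]
            + genome.sequence[ds - 1 : de]
            + mutant.sequence[ds - 1 :]
        )
        restored = restored[: pos - 1] + ref + restored[pos:]
        assert restored == genome.sequence
        assert mpos == pos  # SNP left of the deletion keeps its coordinate

    def test_ref_mismatch_names_position(self):
        genome = GenomeRecord("g", "ACGT" * 10)
        with pytest.raises(ValidationError, match="7"):
            build_mutant_genome(genome, (20, 19), [(7, "A", "T")])

    def test_snp_inside_deletion_rejected(self):
        genome = random_genome(100, seed=49)
        ref = genome.sequence[49]
        with pytest.raises(ValidationError):
            build_mutant_genome(genome, (40, 60), [(50, ref, "A")])

    def test_liftover_monotone_bijective_outside_deletion(self):
        lift_interval = (40, 60)
        genome = random_genome(100, seed=50)
        _, lift = build_mutant_genome(genome, lift_interval)
        mapped = [lift.wild_to_mutant(p) for p in range(1, 101)]
        kept = [m for m in mapped if m is not None]
        assert kept == sorted(kept)
        assert len(set(kept)) == len(kept)
        assert all(mapped[p - 1] is None for p in range(40, 61))
        for p in (1, 39, 61, 100):
            assert lift.mutant_to_wild(lift.wild_to_mutant(p)) == p


class TestSnpEffect:
    def _genome(self, cds_seq, pad=30, strand="+", seed=51):
        body = cds_seq if strand == "+" else revcomp(cds_seq)
        left = random_genome(pad, seed=seed).sequence
        right = random_genome(pad, seed=seed + 1).sequence
        genome = GenomeRecord("g", left + body + right)
        gene = GeneFeature("gene1", pad + 1, pad + len(body), strand, "CDS")
        return genome, [gene]

    def test_wobble_position_synonymous(self):
        genome, feats = self._genome("ATGACATAA")
        # codon 2 third base: ACA -> ACG, both Thr
        pos = 30 + 6
        [eff] = annotate_snp_effect(genome, feats, (pos, "A", "G"))
        assert eff.region == "CDS"
        assert eff.codon_index == 2
        assert eff.aa_change == "synonymous"

    def test_missense_three_letter_notation(self):
        genome, feats = self._genome("ATGACATAA")
        # codon 2 second base: ACA (Thr) -> ATA (Ile)
        pos = 30 + 5
        [eff] = annotate_snp_effect(genome, feats, (pos, "C", "T"))
        assert eff.aa_change == "Thr2Ile"
        assert eff.gene == "gene1"

    def test_minus_strand_cds(self):
        genome, feats = self._genome("ATGACATAA", strand="-")
        # gene body is revcomp(ATGACATAA) on + strand; codon 2 second base
        # (CDS coordinates) sits at genomic position end - 4
        gene = feats[0]
        pos = gene.end - 4
        # genomic base there is complement of CDS 'C'; C->T in CDS space is
        # G->A in genome space
        assert genome.sequence[pos - 1] == "G"
        [eff] = annotate_snp_effect(genome, feats, (pos, "G", "A"))
        assert eff.codon_index == 2
        assert eff.aa_change == "Thr2Ile"

    def test_intergenic_snp(self):
        genome, feats = self._genome("ATGACATAA")
        ref = genome.sequence[4]
        alt = "A" if ref != "A" else "C"
        [eff] = annotate_snp_effect(genome, feats, (5, ref, alt))
        assert eff.region == "intergenic"
        assert eff.gene is None

    def test_overlapping_cds_report_all(self):
        genome = GenomeRecord("g", "ATGATGACATAAGGG")
        feats = [
            GeneFeature("a", 1, 12, "+", "CDS"),
            GeneFeature("b", 4, 15, "+", "CDS"),
        ]
        effects = annotate_snp_effect(genome, feats, (8, "C", "T"))
        assert {e.gene for e in effects} == {"a", "b"}

    def test_nonsense_reported_as_stop(self):
        genome, feats = self._genome("ATGTACTAA")
        # codon 2 TAC (Tyr) -> TAA (stop)
        pos = 30 + 6
        [eff] = annotate_snp_effect(genome, feats, (pos, "C", "A"))
        assert eff.aa_change == "Tyr2Stop"

    def test_retranslation_self_oracle(self):
        from Bio.Seq import Seq

        genome, feats = self._genome("ATGACAGGGTTTTAA")
        gene = feats[0]
        pos, alt = gene.start + 7, "A"  # codon 3 second base G->A
        ref = genome.sequence[pos - 1]
        [eff] = annotate_snp_effect(genome, feats, (pos, ref, alt))
        mutated = (
            genome.sequence[gene.start - 1 : pos - 1]
            + alt
            + genome.sequence[pos : gene.end]
        )
        wt_aa = str(Seq(genome.sequence[gene.start - 1 : gene.end]).translate())
        mut_aa = str(Seq(mutated).translate())
        idx = eff.codon_index - 1
        assert wt_aa[idx] != mut_aa[idx]
        from Bio.SeqUtils import seq3

        assert eff.aa_change == f"{seq3(wt_aa[idx])}{eff.codon_index}{seq3(mut_aa[idx])}"
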