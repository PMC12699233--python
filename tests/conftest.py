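
import numpy as np
import pytest

from kmotif import GeneFeature, GenomeRecord

BASES = "ACGT"


def random_genome(length: int, seed: int, gc: float = 0.5, genome_id: str = "rand") -> GenomeRecord:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(BASES[i] for i in rng.choice(4, size=length, p=p))
    return GenomeRecord(genome_id=genome_id, sequence=seq)


@pytest.fixture
def toy_genbank(tmp_path):
    """Hand-written 3-gene GenBank flat file (120 bp)."""
    seq = ("atgcatgcatgcatgcatgcatgcatgcatgcatgcatgc" * 3)[:120]
    lines = [
        "LOCUS       toyphage                 120 bp    DNA     linear   PHG 01-JAN-2025",
        "DEFINITION  toy phage.",
        "ACCESSION   toyphage",
        "VERSION     toyphage.1",
        "FEATURES             Location/Qualifiers",
        "     source          1..120",
        "     CDS             10..39",
        '                     /locus_tag="t_001"',
        '                     /product="alpha"',
        "     CDS             complement(50..79)",
        '                     /locus_tag="t_002"',
        "     CDS             join(90..100,105..115)",
        '                     /locus_tag="t_003"',
        "ORIGIN",
    ]
    for i in range(0, 120, 60):
        chunk = seq[i : i + 60]
        parts = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {parts}")
    lines.append("//")
    text = "\n".join(lines) + "\n"
    path = tmp_path / "toy.gbk"
    path.write_text(text)
    return path


@pytest.fixture
def simple_features():
    return [
        GeneFeature("g1", 200, 500, "+"),
        GeneFeature("g2", 700, 1000, "+"),
        GeneFeature("g3", 1200, 1500, "-"),
    ]
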