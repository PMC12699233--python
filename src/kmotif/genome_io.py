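"""Genome and annotation I/O, genome-level statistics, and hit export.

Coordinates are 1-based inclusive everywhere internally and in TSV/GFF3
output; only BED export uses the 0-based half-open convention. This matches
the GenBank idiom in which phage genome coordinates are normally quoted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from kmotif.errors import FormatError, UsageError, ValidationError

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    """One phage genome: identity, uppercase sequence and topology."""

    genome_id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValidationError(
                f"{self.genome_id}: sequence contains non-ACGTN characters: "
                f"{sorted(bad)}"
            )
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.genome_id}: empty sequence")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature with 1-based inclusive coordinates.

    The translation start is ``start`` for a + strand feature and ``end``
    for a − strand feature.
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    feature_kind: str = "CDS"
    product: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.locus_tag}: invalid interval [{self.start},{self.end}]"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.locus_tag}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def translation_start(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class GenomeStats:
    length_bp: int
    gc_percent: float
    orf_count: int
    coding_bp: int

    @property
    def coding_fraction_percent(self) -> float:
        return 100.0 * self.coding_bp / self.length_bp


@dataclass(frozen=True)
class GenomeMeta:
    genome_id: str
    cluster: str
    subcluster: str


def _validate_features(
    features: Sequence[GeneFeature], length_bp: int, genome_id: str
) -> None:
    for f in features:
        if f.end > length_bp:
            raise ValidationError(
                f"{genome_id}: feature {f.locus_tag} end {f.end} exceeds "
                f"genome length {length_bp}"
            )


def _feature_from_seqfeature(feat, idx: int) -> GeneFeature:
    loc = feat.location
    if isinstance(loc, CompoundLocation):
        warnings.warn(
            f"compound (join) location flattened to outermost span for "
            f"feature #{idx}",
            stacklevel=2,
        )
    start = int(loc.start) + 1  # Biopython is 0-based half-open
    end = int(loc.end)
    strand = "-" if loc.strand == -1 else "+"
    quals = feat.qualifiers
    locus = (
        quals.get("locus_tag", [None])[0]
        or quals.get("gene", [None])[0]
        or quals.get("protein_id", [None])[0]
        or f"feat_{idx:05d}"
    )
    product = quals.get("product", [""])[0]
    kind = feat.type if feat.type in {"CDS", "gene"} else "other"
    return GeneFeature(
        locus_tag=locus, start=start, end=end, strand=strand,
        feature_kind=kind, product=product,
    )


def read_genbank(path) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Read a single-record GenBank flat file.

    Returns the uppercased sequence and all CDS/gene features with 1-based
    inclusive coordinates. Compound (join) locations are flattened to their
    outermost span with a warning. A record without an ORIGIN sequence block
    raises :class:`FormatError`.
    """
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise FormatError(f"{path}: no GenBank record found")
    try:
        seq = str(rec.seq).upper()
    except Exception:
        raise FormatError(f"{path}: GenBank record has no sequence block")
    if not seq:
        raise FormatError(f"{path}: GenBank record has no sequence block")
    genome = GenomeRecord(genome_id=rec.id or rec.name, sequence=seq)
    features = [
        _feature_from_seqfeature(f, i)
        for i, f in enumerate(rec.features)
        if f.type in {"CDS", "gene"}
    ]
    _validate_features(features, genome.length_bp, genome.genome_id)
    return genome, features


def read_fasta_with_gff(fasta_path, gff_path) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Read a single-sequence FASTA plus its GFF3 annotation.

    The GFF3 seqid column must match the FASTA header id. Same output
    contract as :func:`read_genbank`.
    """
    recs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(recs) != 1:
        raise FormatError(f"{fasta_path}: expected exactly one sequence, got {len(recs)}")
    rec = recs[0]
    genome = GenomeRecord(genome_id=rec.id, sequence=str(rec.seq).upper())
    features = _read_gff3(gff_path, genome)
    return genome, features


def _read_gff3(gff_path, genome: GenomeRecord) -> list[GeneFeature]:
    try:
        db = gffutils.create_db(
            str(gff_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises plain ValueError on bad input
        text = Path(gff_path).read_text()
        if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
            return []  # annotation-free genome is legitimate
        raise FormatError(f"{gff_path}: cannot parse GFF3 ({exc})")
    features: list[GeneFeature] = []
    idx = 0
    for feat in db.all_features(order_by=("start",)):
        if feat.seqid != genome.genome_id:
            raise ValidationError(
                f"{gff_path}: seqid {feat.seqid!r} does not match genome id "
                f"{genome.genome_id!r}"
            )
        if feat.featuretype not in {"CDS", "gene"}:
            continue
        attrs = feat.attributes
        locus = (
            attrs.get("locus_tag", [None])[0]
            or attrs.get("ID", [None])[0]
            or attrs.get("Name", [None])[0]
            or f"feat_{idx:05d}"
        )
        features.append(
            GeneFeature(
                locus_tag=locus,
                start=feat.start,
                end=feat.end,
                strand="-" if feat.strand == "-" else "+",
                feature_kind=feat.featuretype,
                product=attrs.get("product", [""])[0],
            )
        )
        idx += 1
    _validate_features(features, genome.length_bp, genome.genome_id)
    return features


def coding_features(features: Sequence[GeneFeature]) -> list[GeneFeature]:
    """The features that define ORFs: CDS if any exist, otherwise gene
    features (with a logged warning — deposited phage records vary)."""
    cds = [f for f in features if f.feature_kind == "CDS"]
    if cds:
        return cds
    genes = [f for f in features if f.feature_kind == "gene"]
    if genes:
        logger.warning("no CDS features; falling back to %d gene features", len(genes))
    return genes


def genome_stats(genome: GenomeRecord, features: Sequence[GeneFeature]) -> GenomeStats:
    """Length, GC%, ORF count and total coding span.

    GC% is computed over non-N bases. Coding bp sums CDS interval lengths
    per feature (overlaps counted once per feature, i.e. a "collectively
    spanning" total, not a union).
    """
    _validate_features(features, genome.length_bp, genome.genome_id)
    seq = genome.sequence
    gc = seq.count("G") + seq.count("C")
    non_n = genome.length_bp - seq.count("N")
    if non_n == 0:
        raise ValidationError(f"{genome.genome_id}: all-N sequence has no GC content")
    orfs = coding_features(features)
    coding_bp = sum(f.length for f in orfs)
    return GenomeStats(
        length_bp=genome.length_bp,
        gc_percent=100.0 * gc / non_n,
        orf_count=len(orfs),
        coding_bp=coding_bp,
    )


def write_fasta(genome: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.genome_id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_gff3(features: Sequence[GeneFeature], genome_id: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{genome_id}\tkmotif\t{f.feature_kind}\t{f.start}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attrs}\n"
            )


def read_metadata(path) -> pd.DataFrame:
    """Genome→cluster/subcluster table (TSV with columns genome_id, cluster,
    subcluster)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"genome_id", "cluster", "subcluster"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    dup = df["genome_id"][df["genome_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate genome_id rows: {sorted(set(dup))}")
    return df


# ---------------------------------------------------------------------------
# Hit export. SAS hits are simple intervals; ESAS hits are written to GFF3 as
# a parent spanning left repeat + spacer + right repeat with two child repeat
# features.

_SAS_COLUMNS = [
    "genome_id", "start", "end", "strand", "mismatches", "score", "observed",
    "category", "associated_gene", "distance_to_start",
]
_ESAS_COLUMNS = [
    "genome_id", "left_start", "left_end", "right_start", "right_end",
    "spacer_len", "repeat_len", "pair_mismatches", "left_seq", "right_seq",
    "associated_sas", "start_codon_coincident",
]


def _is_esas(hit) -> bool:
    return hasattr(hit, "pair_mismatches")


def hits_to_frame(hits: Sequence) -> pd.DataFrame:
    """Tabulate SAS or ESAS hits (optionally paired with classifications)."""
    rows = []
    for item in hits:
        if isinstance(item, tuple):
            hit, cls = item
        else:
            hit, cls = item, None
        if _is_esas(hit):
            rows.append({c: getattr(hit, c) for c in _ESAS_COLUMNS})
        else:
            row = {
                "genome_id": hit.genome_id, "start": hit.start, "end": hit.end,
                "strand": hit.strand, "mismatches": hit.mismatches,
                "score": hit.score, "observed": hit.observed,
                "category": cls.category if cls else "",
                "associated_gene": (cls.associated_gene or "") if cls else "",
                "distance_to_start": (
                    "" if cls is None or cls.distance_to_start is None
                    else cls.distance_to_start
                ),
            }
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=_SAS_COLUMNS)
    return pd.DataFrame(rows)


def write_hits(hits: Sequence, fmt: str, path, header_params: dict | None = None) -> None:
    """Write hits as TSV (1-based inclusive), BED6 (0-based half-open) or
    GFF3 (1-based inclusive). Conversions are exact and round-trip."""
    fmt = fmt.upper()
    if fmt not in {"TSV", "BED", "GFF3"}:
        raise UsageError(f"unknown output format: {fmt}")
    path = Path(path)
    if fmt == "TSV":
        df = hits_to_frame(hits)
        with open(path, "w") as fh:
            for k, v in (header_params or {}).items():
                fh.write(f"# {k}={v}\n")
            df.to_csv(fh, sep="\t", index=False)
        return
    with open(path, "w") as fh:
        if fmt == "GFF3":
            fh.write("##gff-version 3\n")
        for k, v in (header_params or {}).items():
            fh.write(f"# {k}={v}\n")
        for i, item in enumerate(hits):
            hit = item[0] if isinstance(item, tuple) else item
            if _is_esas(hit):
                if fmt == "BED":
                    fh.write(
                        f"{hit.genome_id}\t{hit.left_start - 1}\t{hit.right_end}"
                        f"\tESAS_{i:04d}\t{hit.pair_mismatches}\t+\n"
                    )
                else:
                    pid = f"ESAS_{i:04d}"
                    fh.write(
                        f"{hit.genome_id}\tkmotif\tmobile_genetic_element\t"
                        f"{hit.left_start}\t{hit.right_end}\t"
                        f"{hit.pair_mismatches}\t+\t.\tID={pid};"
                        f"spacer_len={hit.spacer_len}\n"
                    )
                    fh.write(
                        f"{hit.genome_id}\tkmotif\tinverted_repeat\t"
                        f"{hit.left_start}\t{hit.left_end}\t.\t+\t.\t"
                        f"ID={pid}.L;Parent={pid};side=left\n"
                    )
                    fh.write(
                        f"{hit.genome_id}\tkmotif\tinverted_repeat\t"
                        f"{hit.right_start}\t{hit.right_end}\t.\t+\t.\t"
                        f"ID={pid}.R;Parent={pid};side=right\n"
                    )
            else:
                if fmt == "BED":
                    fh.write(
                        f"{hit.genome_id}\t{hit.start - 1}\t{hit.end}\t"
                        f"SAS_mm{hit.mismatches}\t{hit.score}\t{hit.strand}\n"
                    )
                else:
                    fh.write(
                        f"{hit.genome_id}\tkmotif\tsequence_motif\t{hit.start}"
                        f"\t{hit.end}\t{hit.score}\t{hit.strand}\t.\t"
                        f"ID=SAS_{i:04d};mismatches={hit.mismatches};"
                        f"observed={hit.observed}\n"
                    )


def read_sas_hits_tsv(path) -> list:
    """Round-trip reader for SAS hit TSVs written by :func:`write_hits`.

    Returns ``(SASHit, HitClassification | None)`` pairs.
    """
    from kmotif.sas import HitClassification, SASHit

    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, r in df.iterrows():
        hit = SASHit(
            genome_id=str(r["genome_id"]), start=int(r["start"]),
            end=int(r["end"]), strand=str(r["strand"]),
            mismatches=int(r["mismatches"]), observed=str(r["observed"]),
        )
        cls = None
        if "category" in df.columns and isinstance(r["category"], str) and r["category"]:
            dist = r.get("distance_to_start")
            cls = HitClassification(
                category=str(r["category"]),
                associated_gene=(
                    str(r["associated_gene"])
                    if isinstance(r["associated_gene"], str) and r["associated_gene"]
                    else None
                ),
                distance_to_start=None if pd.isna(dist) or dist == "" else int(dist),
            )
        out.append((hit, cls))
    return out


def read_esas_hits_tsv(path) -> list:
    """Round-trip reader for ESAS hit TSVs written by :func:`write_hits`."""
    from kmotif.esas import ESASHit

    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, r in df.iterrows():
        assoc = r.get("associated_sas")
        out.append(
            ESASHit(
                genome_id=str(r["genome_id"]),
                left_start=int(r["left_start"]), left_end=int(r["left_end"]),
                right_start=int(r["right_start"]), right_end=int(r["right_end"]),
                spacer_len=int(r["spacer_len"]), repeat_len=int(r["repeat_len"]),
                pair_mismatches=int(r["pair_mismatches"]),
                left_seq=str(r["left_seq"]), right_seq=str(r["right_seq"]),
                associated_sas=(
                    None if pd.isna(assoc) or assoc == "" else str(assoc)
                ),
                start_codon_coincident=bool(r["start_codon_coincident"]),
            )
        )
    return out
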