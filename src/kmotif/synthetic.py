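"""Download-free fixture genomes with planted SAS/ESAS elements.

The generator emulates the shape of a cluster K mycobacteriophage genome —
by default ~58 kb, 67% GC, 94 densely packed and almost entirely
forward-strand CDS features — and plants consensus motifs at controlled
mismatch counts and offsets upstream of gene starts, and inverted-repeat
pairs with controlled mismatches and spacers. Every planted element is
recorded in a truth table so scanner recall can be asserted exactly.

The background is i.i.d. with a GC knob (no dinucleotide structure); planted
elements carry *exactly* the requested Hamming distance, enforced by
post-generation verification with local background redraws so that no
accidental closer match arises in the immediate neighbourhood of a plant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from kmotif.errors import UsageError, ValidationError
from kmotif.genome_io import GeneFeature, GenomeRecord
from kmotif.sas import DEFAULT_CONSENSUS
from kmotif.seqops import hamming, revcomp

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedSAS:
    """A consensus copy planted upstream of a gene.

    ``offset_upstream`` is the nt gap between the motif and the gene's
    translation start; ``mismatches`` is the exact Hamming distance of the
    planted copy from the consensus.
    """

    gene_index: int
    offset_upstream: int
    mismatches: int = 0


@dataclass(frozen=True)
class PlantedESAS:
    """An inverted-repeat pair planted at a fixed position or snapped to a
    gene start.

    With ``boundary_coincident`` the element is placed so its right repeat
    ends exactly on the first nucleotide of gene ``gene_index``'s start
    codon and ``position`` is ignored. ``with_sas`` additionally plants an
    exact consensus copy ending 10 nt before the left repeat.
    """

    position: Optional[int] = None  # left_start, 1-based
    spacer_len: int = 4
    pair_mismatches: int = 0
    with_sas: bool = False
    boundary_coincident: bool = False
    gene_index: Optional[int] = None


@dataclass(frozen=True)
class FixtureSpec:
    """Study-shaped synthetic genome: defaults mirror a cluster K phage."""

    length_bp: int = 57_978
    gc_percent: float = 67.0
    n_genes: int = 94
    forward_strand_fraction: float = 0.97
    intergenic_gap: int = 35  # dense packing: ~93.5% coding at the defaults
    planted_sas: tuple[PlantedSAS, ...] = ()
    planted_esas: tuple[PlantedESAS, ...] = ()
    seed: int = 0
    genome_id: str = "synthetic_K"
    consensus: str = DEFAULT_CONSENSUS
    repeat_len: int = 17


TRUTH_COLUMNS = [
    "kind", "start", "end", "strand", "mismatches", "spacer_len",
    "classification", "gene",
]


def neighborhood_size(consensus_len: int, max_mm: int) -> int:
    """Number of distinct sequences within Hamming distance max_mm of a
    fixed consensus: Σ_{i=0..max_mm} C(len, i) · 3^i."""
    if max_mm > consensus_len:
        raise UsageError("max_mm exceeds consensus length")
    return sum(math.comb(consensus_len, i) * 3**i for i in range(max_mm + 1))


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    """Exactly n_mut substitutions at distinct random positions."""
    if n_mut > len(seq):
        raise ValidationError(f"cannot place {n_mut} mismatches in {len(seq)} nt")
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in _BASES if b != out[p]]
        out[p] = choices[rng.integers(3)]
    return "".join(out)


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p_gc = gc / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    idx = rng.choice(4, size=n, p=probs)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].copy()


class _Occupancy:
    """Non-overlap bookkeeping for planted intervals (1-based inclusive)."""

    def __init__(self, length_bp: int):
        self.length_bp = length_bp
        self.intervals: list[tuple[int, int, str]] = []

    def claim(self, start: int, end: int, label: str) -> None:
        if not (1 <= start <= end <= self.length_bp):
            raise ValidationError(f"{label}: [{start},{end}] out of bounds")
        for s, e, other in self.intervals:
            if start <= e and s <= end:
                raise ValidationError(
                    f"{label}: [{start},{end}] overlaps {other} [{s},{e}]"
                )
        self.intervals.append((start, end, label))


def _layout_genes(spec: FixtureSpec, rng: np.random.Generator) -> list[GeneFeature]:
    margin, gap = 250, spec.intergenic_gap
    avail = spec.length_bp - 2 * margin - (spec.n_genes - 1) * gap
    gene_len = (avail // spec.n_genes) // 3 * 3
    if gene_len < 60:
        raise ValidationError(
            f"{spec.n_genes} genes do not fit in {spec.length_bp} bp"
        )
    features = []
    pos = margin + 1
    for i in range(spec.n_genes):
        strand = "+" if rng.random() < spec.forward_strand_fraction else "-"
        features.append(
            GeneFeature(
                locus_tag=f"syn_{i + 1:05d}",
                start=pos,
                end=pos + gene_len - 1,
                strand=strand,
                feature_kind="CDS",
                product="hypothetical protein",
            )
        )
        pos += gene_len + gap
    return features


def _write(arr: np.ndarray, start: int, s: str) -> None:
    arr[start - 1 : start - 1 + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)


def _local_scan(arr: np.ndarray, consensus: str, lo: int, hi: int) -> dict[tuple[int, str], int]:
    """Hamming distances for all windows with 1-based start in [lo, hi]."""
    from kmotif.seqops import window_mismatches

    k = len(consensus)
    lo = max(lo, 1)
    hi = min(hi, arr.size - k + 1)
    out: dict[tuple[int, str], int] = {}
    if hi < lo:
        return out
    sub = arr[lo - 1 : hi - 1 + k]
    for strand, pat in (("+", consensus), ("-", revcomp(consensus))):
        mm = window_mismatches(sub, pat.encode())
        for i, m in enumerate(mm):
            out[(lo + i, strand)] = int(m)
    return out


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[GenomeRecord, list[GeneFeature], pd.DataFrame]:
    """Generate (genome, CDS features, truth table).

    Deterministic under a fixed seed. Raises on infeasible specs (planted
    elements overlapping each other or falling out of bounds).
    """
    rng = np.random.default_rng(spec.seed)
    # the forced start/stop codons (6 nt per gene, exactly 1 G/C among them)
    # are AT-rich; compensate the background draw so the whole-genome GC
    # expectation equals the requested target
    n_forced = 6 * spec.n_genes
    target_gc = spec.gc_percent / 100.0 * spec.length_bp
    bg_gc = 100.0 * (target_gc - spec.n_genes) / max(spec.length_bp - n_forced, 1)
    arr = _random_seq(spec.length_bp, min(max(bg_gc, 0.0), 100.0), rng)
    features = _layout_genes(spec, rng)
    occ = _Occupancy(spec.length_bp)
    k = len(spec.consensus)
    R = spec.repeat_len

    # start/stop codons for cosmetic realism
    for f in features:
        if f.strand == "+":
            _write(arr, f.start, "ATG")
            _write(arr, f.end - 2, "TAA")
        else:
            _write(arr, f.start, "TTA")
            _write(arr, f.end - 2, "CAT")

    truth_rows: list[dict] = []

    def plant_sas(gene: GeneFeature, offset: int, n_mm: int, classification: str) -> None:
        motif = _mutate(spec.consensus, n_mm, rng)
        if gene.strand == "+":
            end = gene.start - 1 - offset
            start = end - k + 1
            strand = "+"
            written = motif
        else:
            start = gene.end + 1 + offset
            end = start + k - 1
            strand = "-"
            written = revcomp(motif)
        occ.claim(start, end, f"SAS@{gene.locus_tag}")
        _write(arr, start, written)
        _guard_neighborhood(start, n_mm)
        truth_rows.append(
            dict(kind="SAS", start=start, end=end, strand=strand,
                 mismatches=n_mm, spacer_len=pd.NA,
                 classification=classification, gene=gene.locus_tag)
        )

    def _redrawable(pos: int) -> bool:
        # background positions only: in bounds and inside no claimed interval
        if not 1 <= pos <= spec.length_bp:
            return False
        return not any(s <= pos <= e for s, e, _ in occ.intervals)

    def _guard_neighborhood(p_start: int, planted_mm: int) -> None:
        # No window overlapping the plant (other than the plant itself) may
        # match the consensus within the scan budget: otherwise a planted
        # motif would be shadowed by an accidental closer neighbour. On
        # violation the unclaimed flanking background is redrawn.
        for _ in range(50):
            dists = _local_scan(arr, spec.consensus, p_start - k + 1, p_start + k - 1)
            bad = [
                key for key, m in dists.items()
                if key[0] != p_start and m <= max(planted_mm, 2)
            ]
            if not bad:
                return
            for pos in range(p_start - k, p_start + 2 * k):
                if _redrawable(pos) and not (p_start <= pos < p_start + k):
                    arr[pos - 1] = _random_seq(1, spec.gc_percent, rng)[0]
        raise ValidationError("could not isolate a planted motif from background")

    for p in spec.planted_sas:
        if not 0 <= p.gene_index < len(features):
            raise ValidationError(f"planted SAS gene_index {p.gene_index} out of range")
        plant_sas(features[p.gene_index], p.offset_upstream, p.mismatches, "upstream")

    for p in spec.planted_esas:
        if p.boundary_coincident:
            if p.gene_index is None:
                raise ValidationError("boundary_coincident plant needs gene_index")
            gene = features[p.gene_index]
            if gene.strand == "+":
                right_end = gene.start
                left_start = right_end - (2 * R + p.spacer_len) + 1
            else:
                left_start = gene.end
                right_end = left_start + 2 * R + p.spacer_len - 1
        else:
            if p.position is None:
                raise ValidationError("non-coincident plant needs a position")
            left_start = p.position
            right_end = left_start + 2 * R + p.spacer_len - 1
        left_end = left_start + R - 1
        right_start = right_end - R + 1
        occ.claim(left_start, right_end, "ESAS")
        left = "".join(_BASES[i] for i in rng.integers(4, size=R))
        right = _mutate(revcomp(left), p.pair_mismatches, rng)
        _write(arr, left_start, left)
        _write(arr, right_start, right)
        truth_rows.append(
            dict(kind="ESAS", start=left_start, end=right_end, strand="+",
                 mismatches=p.pair_mismatches, spacer_len=p.spacer_len,
                 classification="boundary" if p.boundary_coincident else "",
                 gene=(features[p.gene_index].locus_tag
                       if p.gene_index is not None else ""))
        )
        if p.with_sas:
            sas_end = left_start - 11
            sas_start = sas_end - k + 1
            occ.claim(sas_start, sas_end, "SAS-for-ESAS")
            _write(arr, sas_start, spec.consensus)
            _guard_neighborhood(sas_start, 0)
            truth_rows.append(
                dict(kind="SAS", start=sas_start, end=sas_end, strand="+",
                     mismatches=0, spacer_len=pd.NA,
                     classification="esas_associated", gene="")
            )

    # re-verify every planted SAS still has its exact distance (a later plant
    # or codon write could in principle collide; occupancy should prevent it)
    for row in truth_rows:
        if row["kind"] != "SAS":
            continue
        window = arr[row["start"] - 1 : row["end"]].tobytes().decode()
        obs = window if row["strand"] == "+" else revcomp(window)
        if hamming(obs, spec.consensus) != row["mismatches"]:
            raise ValidationError(
                f"planted SAS at {row['start']} corrupted during generation"
            )

    genome = GenomeRecord(
        genome_id=spec.genome_id, sequence=arr.tobytes().decode("ascii")
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if not truth.empty:
        truth = truth.astype(
            {"start": "int64", "end": "int64", "mismatches": "int64",
             "spacer_len": "Int64"}
        )
    return genome, features, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"kind": str, "start": "int64", "end": "int64", "strand": str,
               "mismatches": "int64", "spacer_len": "Int64",
               "classification": str, "gene": str},
        keep_default_na=False, na_values=[""],
    )
    df["classification"] = df["classification"].fillna("")
    df["gene"] = df["gene"].fillna("")
    return df[TRUTH_COLUMNS]
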