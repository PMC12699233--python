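"""Start-Associated Sequence (SAS) scanning and gene-start classification.

SAS motifs are occurrences of a short degenerate consensus (default
``GGGATAGGAGCCC``) within a Hamming-distance budget (default 2 mismatches;
an extended search uses 3). Hits are classified relative to annotated coding
features as *upstream* (wholly inside a window before a gene's translation
start, on the gene's strand), *intragenic* (overlapping any CDS on either
strand) or *distal*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from kmotif.errors import UsageError, ValidationError
from kmotif.genome_io import GeneFeature, GenomeRecord, coding_features
from kmotif.seqops import hamming, revcomp, to_bytes, window_mismatches

DEFAULT_CONSENSUS = "GGGATAGGAGCCC"
DEFAULT_UPSTREAM_WINDOW = 100


@dataclass(frozen=True)
class ConsensusMotif:
    """A degenerate consensus with a mismatch budget."""

    sequence: str = DEFAULT_CONSENSUS
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValidationError("consensus must be over {A,C,G,T}")
        if not 0 <= self.max_mismatches <= len(self.sequence):
            raise ValidationError(
                f"max_mismatches {self.max_mismatches} outside "
                f"[0, {len(self.sequence)}]"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SASHit:
    """One consensus occurrence.

    ``observed`` is the genomic window read in motif orientation (reverse
    complemented for − strand hits), so Hamming(observed, consensus) equals
    ``mismatches``. ``score`` is consensus length − mismatches.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    observed: str

    @property
    def score(self) -> int:
        return (self.end - self.start + 1) - self.mismatches

    @property
    def hit_id(self) -> str:
        return f"SAS:{self.start}:{self.strand}"


@dataclass(frozen=True)
class HitClassification:
    category: str  # upstream | intragenic | distal
    associated_gene: Optional[str] = None
    distance_to_start: Optional[int] = None  # nt gap motif→start (upstream only)


def scan_consensus(
    genome: GenomeRecord,
    motif: ConsensusMotif = ConsensusMotif(),
    strands: str = "both",
) -> list[SASHit]:
    """Every window (per requested strand) within the mismatch budget.

    A − strand hit at genomic interval [s, e] means revcomp(genome[s..e])
    matches the consensus; one genomic window can therefore yield one hit on
    each strand (quasi-palindromic consensus), and both are reported. Output
    is sorted by start, + before − at equal start. A genome shorter than the
    consensus yields an empty list.
    """
    if strands not in {"+", "-", "both"}:
        raise UsageError(f"strands must be +, - or both, not {strands!r}")
    k = motif.length
    if genome.length_bp < k:
        import warnings

        warnings.warn(
            f"{genome.genome_id}: genome shorter than consensus; no scan",
            stacklevel=2,
        )
        return []
    arr = to_bytes(genome.sequence)
    hits: list[SASHit] = []
    patterns = []
    if strands in {"+", "both"}:
        patterns.append(("+", motif.sequence))
    if strands in {"-", "both"}:
        patterns.append(("-", revcomp(motif.sequence)))
    for strand, pattern in patterns:
        mm = window_mismatches(arr, pattern.encode("ascii"))
        for i in (mm <= motif.max_mismatches).nonzero()[0]:
            start = int(i) + 1
            window = genome.sequence[i : i + k]
            observed = window if strand == "+" else revcomp(window)
            hits.append(
                SASHit(
                    genome_id=genome.genome_id,
                    start=start,
                    end=start + k - 1,
                    strand=strand,
                    mismatches=int(mm[i]),
                    observed=observed,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand != "+"))
    return hits


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def classify_hits(
    hits: Sequence[SASHit],
    features: Sequence[GeneFeature],
    upstream_window_nt: int = DEFAULT_UPSTREAM_WINDOW,
) -> list[tuple[SASHit, HitClassification]]:
    """Classify each hit as intragenic, upstream or distal.

    A hit overlapping any coding interval (either strand) is intragenic —
    this includes hits overlapping a start codon. Otherwise, a hit lying
    wholly within the ``upstream_window_nt`` window before some gene's
    translation start *on that gene's strand* is upstream of the nearest such
    gene (ties by smallest gap, then lexicographically lowest locus_tag);
    the recorded distance is the nt gap between motif and start codon.
    Everything else is distal.
    """
    orfs = coding_features(features)
    out: list[tuple[SASHit, HitClassification]] = []
    for hit in hits:
        overlapping = [f for f in orfs if _overlaps(hit.start, hit.end, f.start, f.end)]
        if overlapping:
            host = min(overlapping, key=lambda f: (f.start, f.locus_tag))
            out.append((hit, HitClassification("intragenic", host.locus_tag)))
            continue
        candidates: list[tuple[int, str]] = []
        for f in orfs:
            if f.strand != hit.strand:
                continue
            if f.strand == "+":
                lo, hi = f.start - upstream_window_nt, f.start - 1
                gap = f.start - hit.end - 1
            else:
                lo, hi = f.end + 1, f.end + upstream_window_nt
                gap = hit.start - f.end - 1
            if hit.start >= lo and hit.end <= hi:
                candidates.append((gap, f.locus_tag))
        if candidates:
            gap, locus = min(candidates)
            out.append((hit, HitClassification("upstream", locus, gap)))
        else:
            out.append((hit, HitClassification("distal")))
    return out


def top_k_hits(hits: Sequence[SASHit], k: int = 5) -> list[SASHit]:
    """The k best-scoring hits (fewest mismatches); ties broken by leftmost
    start, then + before −. Returns all hits when fewer than k exist."""
    ranked = sorted(hits, key=lambda h: (h.mismatches, h.start, h.strand != "+"))
    return ranked[:k]


def recheck_hit(genome: GenomeRecord, hit: SASHit, motif: ConsensusMotif) -> bool:
    """Re-derive the mismatch count from the sequence (integrity check)."""
    window = genome.sequence[hit.start - 1 : hit.end]
    observed = window if hit.strand == "+" else revcomp(window)
    return (
        observed == hit.observed
        and hamming(observed, motif.sequence) == hit.mismatches
    )
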