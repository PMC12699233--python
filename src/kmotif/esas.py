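"""Extended SAS (ESAS) detection: pairs of imperfect inverted repeats.

An ESAS element is a left repeat of fixed width (default 17 nt), a variable
spacer and a right repeat of the same width, where the left repeat and the
reverse complement of the right repeat agree up to a small number of
mismatches. Detection is exhaustive over all (left_start, spacer) pairs in
the configured spacer range; SAS proximity and gene-start coincidence are
annotations applied afterwards, never detection filters.

Default thresholds (3 pair mismatches, spacer 0–50 nt) are the package's
calibrated values for "imperfect" repeats with a "variable" spacer; both are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from kmotif.errors import UsageError
from kmotif.genome_io import GeneFeature, GenomeRecord, coding_features
from kmotif.sas import SASHit
from kmotif.seqops import complement_bytes, revcomp, to_bytes

DEFAULT_REPEAT_LEN = 17
DEFAULT_MAX_PAIR_MISMATCHES = 3
DEFAULT_SPACER_MIN = 0
DEFAULT_SPACER_MAX = 50
DEFAULT_SAS_PROXIMITY = 50


@dataclass(frozen=True)
class ESASHit:
    """One imperfect inverted-repeat pair.

    ``pair_mismatches`` is Hamming(left_seq, revcomp(right_seq)); both
    repeat sequences are literal + strand genomic substrings.
    """

    genome_id: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    spacer_len: int
    repeat_len: int
    pair_mismatches: int
    left_seq: str
    right_seq: str
    associated_sas: Optional[str] = None
    start_codon_coincident: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return self.left_start, self.right_end


@dataclass(frozen=True)
class RepeatProfile:
    """Per-position base tallies across a set of repeats.

    Positions are numbered 1..repeat_len left-to-right on the literal genomic
    substring (so "the last nucleotide of the right repeat" is position
    repeat_len of the right-side profile).
    """

    side: str
    counts: pd.DataFrame  # index 1..repeat_len, columns A,C,G,T(,N)
    n_sequences: int

    def fraction(self, position: int, base: str) -> float:
        return self.counts.loc[position, base] / self.n_sequences

    def modal_base(self, position: int) -> str:
        return self.counts.loc[position].idxmax()


def scan_inverted_repeats(
    genome: GenomeRecord,
    repeat_len: int = DEFAULT_REPEAT_LEN,
    max_pair_mismatches: int = DEFAULT_MAX_PAIR_MISMATCHES,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
    intergenic_only: bool = False,
    features: Sequence[GeneFeature] | None = None,
) -> list[ESASHit]:
    """Exhaustive imperfect inverted-repeat search.

    Tests every (left_start, spacer_len) with spacer_min ≤ spacer_len ≤
    spacer_max and emits pairs whose left repeat matches the reverse
    complement of the right repeat with ≤ max_pair_mismatches. Candidates
    sharing a left_start are deduplicated keeping the fewest mismatches,
    then the shortest spacer. Output sorted by left_start.

    With ``intergenic_only`` the element's whole span must avoid coding
    intervals (requires ``features``).
    """
    if spacer_min > spacer_max:
        raise UsageError(f"spacer_min {spacer_min} > spacer_max {spacer_max}")
    if spacer_min < 0:
        raise UsageError("spacer_min must be >= 0")
    if intergenic_only and features is None:
        raise UsageError("intergenic_only requires features")
    L = genome.length_bp
    R = repeat_len
    arr = to_bytes(genome.sequence)
    comp = complement_bytes(arr)
    best: dict[int, tuple[int, int]] = {}  # left_start(0b) -> (mm, spacer)
    for s in range(spacer_min, spacer_max + 1):
        n = L - 2 * R - s + 1
        if n <= 0:
            continue
        mm = np.zeros(n, dtype=np.int32)
        # left base j pairs with right base (R-1-j): genomic offset s+2R-1-j
        for j in range(R):
            off = s + 2 * R - 1 - j
            mm += arr[j : j + n] != comp[off : off + n]
        for i in (mm <= max_pair_mismatches).nonzero()[0]:
            i = int(i)
            cand = (int(mm[i]), s)
            if i not in best or cand < best[i]:
                best[i] = cand
    hits: list[ESASHit] = []
    for i in sorted(best):
        pair_mm, s = best[i]
        left_start = i + 1
        left_end = left_start + R - 1
        right_start = left_end + s + 1
        right_end = right_start + R - 1
        hits.append(
            ESASHit(
                genome_id=genome.genome_id,
                left_start=left_start,
                left_end=left_end,
                right_start=right_start,
                right_end=right_end,
                spacer_len=s,
                repeat_len=R,
                pair_mismatches=pair_mm,
                left_seq=genome.sequence[left_start - 1 : left_end],
                right_seq=genome.sequence[right_start - 1 : right_end],
            )
        )
    if intergenic_only:
        orfs = coding_features(features or [])
        hits = [
            h
            for h in hits
            if not any(
                h.left_start <= f.end and f.start <= h.right_end for f in orfs
            )
        ]
    return hits


def associate_with_sas(
    esas_hits: Sequence[ESASHit],
    sas_hits: Sequence[SASHit],
    proximity_nt: int = DEFAULT_SAS_PROXIMITY,
) -> list[ESASHit]:
    """Annotate each element with the nearest SAS hit within proximity_nt of
    its span (annotation only — never a filter)."""
    out: list[ESASHit] = []
    for eh in esas_hits:
        nearest: tuple[int, int, str] | None = None
        for sh in sas_hits:
            if sh.genome_id != eh.genome_id:
                continue
            if sh.end < eh.left_start:
                dist = eh.left_start - sh.end
            elif sh.start > eh.right_end:
                dist = sh.start - eh.right_end
            else:
                dist = 0  # overlapping
            if dist <= proximity_nt:
                key = (dist, sh.start, sh.hit_id)
                if nearest is None or key < nearest:
                    nearest = key
        out.append(replace(eh, associated_sas=nearest[2] if nearest else None))
    return out


def flag_start_codon_coincidence(
    esas_hits: Sequence[ESASHit],
    features: Sequence[GeneFeature],
) -> list[ESASHit]:
    """Flag elements whose outer boundary lands exactly on the first
    nucleotide of a gene's start codon: right_end == start for a + strand
    gene, and (mirrored) left_start == end for a − strand gene."""
    orfs = coding_features(features)
    plus_starts = {f.start for f in orfs if f.strand == "+"}
    minus_starts = {f.end for f in orfs if f.strand == "-"}
    return [
        replace(
            eh,
            start_codon_coincident=(
                eh.right_end in plus_starts or eh.left_start in minus_starts
            ),
        )
        for eh in esas_hits
    ]


def repeat_profile(esas_hits: Sequence[ESASHit], side: str) -> RepeatProfile:
    """Per-position nucleotide tallies of the left or right repeats.

    Both sides are profiled as their literal genomic substrings, positions
    numbered 1..repeat_len left to right.
    """
    if side not in {"left", "right"}:
        raise UsageError(f"side must be 'left' or 'right', not {side!r}")
    if not esas_hits:
        raise UsageError("cannot profile an empty hit set")
    lens = {h.repeat_len for h in esas_hits}
    if len(lens) != 1:
        raise UsageError(f"mixed repeat lengths: {sorted(lens)}")
    (R,) = lens
    seqs = [h.left_seq if side == "left" else h.right_seq for h in esas_hits]
    bases = sorted({b for s in seqs for b in s} | set("ACGT"))
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, R + 1, name="position"), columns=bases
    )
    for s in seqs:
        for pos, b in enumerate(s, start=1):
            counts.loc[pos, b] += 1
    return RepeatProfile(side=side, counts=counts, n_sequences=len(seqs))


def recheck_hit(genome: GenomeRecord, hit: ESASHit) -> bool:
    """Re-derive pair_mismatches from the genome (integrity check)."""
    left = genome.sequence[hit.left_start - 1 : hit.left_end]
    right = genome.sequence[hit.right_start - 1 : hit.right_end]
    from kmotif.seqops import hamming

    return (
        left == hit.left_seq
        and right == hit.right_seq
        and hamming(left, revcomp(right)) == hit.pair_mismatches
    )
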