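"""Cross-subcluster aggregation of per-genome scan results.

Summaries pool hits within each subcluster: the exact-match percentage is
the pooled fraction of 0-mismatch hits among all hits in the subcluster's
genomes (a per-genome mean of percentages is available behind a flag).
Genomes with zero hits contribute 0 to the per-genome mean and nothing to
the exact-match denominator; a subcluster with no hits at all reports the
percentage as missing, not 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from kmotif.errors import ValidationError
from kmotif.esas import ESASHit
from kmotif.sas import HitClassification, SASHit, top_k_hits


@dataclass
class GenomeScanResult:
    """Everything the scanners produced for one genome."""

    genome_id: str
    sas_hits: list[SASHit] = field(default_factory=list)
    classifications: list[Optional[HitClassification]] = field(default_factory=list)
    esas_hits: list[ESASHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classifications:
            self.classifications = [None] * len(self.sas_hits)
        if len(self.classifications) != len(self.sas_hits):
            raise ValidationError(
                f"{self.genome_id}: {len(self.sas_hits)} hits but "
                f"{len(self.classifications)} classifications"
            )


@dataclass(frozen=True)
class SubclusterSummary:
    subcluster: str
    n_genomes: int
    mean_sas_per_genome: float
    exact_match_percent: Optional[float]  # None when the subcluster has no hits
    mismatch_histogram: dict[int, int]
    esas_total: int


def _subcluster_map(results: Sequence[GenomeScanResult], metadata: pd.DataFrame) -> dict[str, str]:
    meta = dict(zip(metadata["genome_id"], metadata["subcluster"]))
    missing = [r.genome_id for r in results if r.genome_id not in meta]
    if missing:
        raise ValidationError(f"genomes without metadata rows: {missing}")
    return meta


def summarize_subclusters(
    results: Sequence[GenomeScanResult],
    metadata: pd.DataFrame,
    per_genome_percent: bool = False,
) -> list[SubclusterSummary]:
    """One summary per subcluster, sorted by subcluster label.

    ``per_genome_percent`` switches exact_match_percent from pooled counting
    (default) to the mean of per-genome percentages over genomes with ≥1 hit.
    """
    meta = _subcluster_map(results, metadata)
    groups: dict[str, list[GenomeScanResult]] = {}
    for r in results:
        groups.setdefault(meta[r.genome_id], []).append(r)
    out: list[SubclusterSummary] = []
    for sub in sorted(groups):
        members = groups[sub]
        counts = [len(r.sas_hits) for r in members]
        hist: dict[int, int] = {}
        for r in members:
            for h in r.sas_hits:
                hist[h.mismatches] = hist.get(h.mismatches, 0) + 1
        total = sum(counts)
        if per_genome_percent:
            percents = [
                100.0 * sum(1 for h in r.sas_hits if h.mismatches == 0) / len(r.sas_hits)
                for r in members
                if r.sas_hits
            ]
            exact = sum(percents) / len(percents) if percents else None
        else:
            exact = 100.0 * hist.get(0, 0) / total if total else None
        out.append(
            SubclusterSummary(
                subcluster=sub,
                n_genomes=len(members),
                mean_sas_per_genome=total / len(members),
                exact_match_percent=exact,
                mismatch_histogram=dict(sorted(hist.items())),
                esas_total=sum(len(r.esas_hits) for r in members),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[SubclusterSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "subcluster": s.subcluster,
            "n_genomes": s.n_genomes,
            "mean_sas_per_genome": s.mean_sas_per_genome,
            "exact_match_percent": (
                math.nan if s.exact_match_percent is None else s.exact_match_percent
            ),
            "esas_total": s.esas_total,
        }
        for mm in (0, 1, 2, 3):
            if mm in s.mismatch_histogram or mm <= 2:
                row[f"mm{mm}"] = s.mismatch_histogram.get(mm, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_table(results: Sequence[GenomeScanResult]) -> pd.DataFrame:
    """One row per genome: mismatch-class counts, positional classification
    counts, ESAS count and the top-5 hit scores (comma-joined)."""
    columns = [
        "genome_id", "n_sas", "mm0", "mm1", "mm2", "mm3plus",
        "upstream", "intragenic", "distal", "unclassified",
        "n_esas", "top5_scores",
    ]
    rows = []
    for r in results:
        mm = {0: 0, 1: 0, 2: 0, "3plus": 0}
        for h in r.sas_hits:
            if h.mismatches <= 2:
                mm[h.mismatches] += 1
            else:
                mm["3plus"] += 1
        cats = {"upstream": 0, "intragenic": 0, "distal": 0, "unclassified": 0}
        for c in r.classifications:
            cats[c.category if c is not None else "unclassified"] += 1
        top5 = top_k_hits(r.sas_hits, 5)
        rows.append(
            {
                "genome_id": r.genome_id,
                "n_sas": len(r.sas_hits),
                "mm0": mm[0], "mm1": mm[1], "mm2": mm[2], "mm3plus": mm["3plus"],
                **cats,
                "n_esas": len(r.esas_hits),
                "top5_scores": ",".join(str(h.score) for h in top5),
            }
        )
    return pd.DataFrame(rows, columns=columns)
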