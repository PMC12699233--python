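"""Reproduction of the published cluster K panel numbers from GenBank records.

Given local GenBank flat files for the eight representative cluster K phages
(Anaya JF704106 K1, ZoeJ KJ510412 K2, Pixie JF937104 K3, Yasnaya_Polyana
PQ495710 K4, Kratio KM923971 K5, Unicorn MF324908 K6, Aminay MH509442 K7,
Boilgate MZ274310 K8), recompute the panel statistics with the package's
default parameters and report each published target's match status.

This module performs no network access; obtaining the records is the
caller's job (see scripts/reproduce_published.py).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from kmotif.errors import ValidationError
from kmotif.esas import flag_start_codon_coincidence, scan_inverted_repeats
from kmotif.esas import associate_with_sas
from kmotif.genome_io import genome_stats, read_genbank
from kmotif.sas import ConsensusMotif, classify_hits, scan_consensus

#: accession (version suffix stripped) -> (phage, subcluster)
PANEL = {
    "JF704106": ("Anaya", "K1"),
    "KJ510412": ("ZoeJ", "K2"),
    "JF937104": ("Pixie", "K3"),
    "PQ495710": ("Yasnaya_Polyana", "K4"),
    "KM923971": ("Kratio", "K5"),
    "MF324908": ("Unicorn", "K6"),
    "MH509442": ("Aminay", "K7"),
    "MZ274310": ("Boilgate", "K8"),
}

YP = "PQ495710"

#: published values the reproduction is checked against
EXPECTED = {
    "yp_length_bp": 57_978,
    "yp_gc_percent_rounded": 67,
    "yp_orf_count": 94,
    "yp_coding_fraction_percent_rounded": 93.7,
    "panel_sas_total_2mm": 125,
    "panel_sas_intra_orf_2mm": 6,
    "yp_sas_upstream_2mm": 7,
    "yp_sas_intragenic_2mm": 2,
    "k8_sas_total_2mm": 0,
    "panel_sas_exactly_3mm": 72,
    "panel_esas_total": 58,
    "yp_esas_total": 7,
    "yp_esas_sas_associated": 1,
    "yp_esas_boundary_coincident": 3,
}


def _find_record(genbank_dir: Path, accession: str) -> Path:
    for pattern in (f"{accession}*.gb", f"{accession}*.gbk", f"{accession}*.genbank"):
        matches = sorted(genbank_dir.glob(pattern))
        if matches:
            return matches[0]
    raise ValidationError(f"no GenBank file for {accession} under {genbank_dir}")


def reproduce_panel(
    genbank_dir,
    upstream_window: int = 100,
    max_pair_mismatches: int = 3,
    spacer_min: int = 0,
    spacer_max: int = 50,
    proximity: int = 50,
) -> dict[str, float]:
    """Recompute every published panel quantity from local GenBank records."""
    genbank_dir = Path(genbank_dir)
    observed: dict[str, float] = {}
    sas2_total = intra2_total = sas3_total = esas_total = 0
    for acc in PANEL:
        genome, features = read_genbank(_find_record(genbank_dir, acc))
        hits2 = scan_consensus(genome, ConsensusMotif(max_mismatches=2))
        hits3 = scan_consensus(genome, ConsensusMotif(max_mismatches=3))
        classified2 = classify_hits(hits2, features, upstream_window)
        esas = scan_inverted_repeats(
            genome, 17, max_pair_mismatches, spacer_min, spacer_max
        )
        sas2_total += len(hits2)
        intra2_total += sum(1 for _, c in classified2 if c.category == "intragenic")
        sas3_total += sum(1 for h in hits3 if h.mismatches == 3)
        esas_total += len(esas)
        if acc == YP:
            st = genome_stats(genome, features)
            observed["yp_length_bp"] = st.length_bp
            observed["yp_gc_percent_rounded"] = round(st.gc_percent)
            observed["yp_orf_count"] = st.orf_count
            observed["yp_coding_fraction_percent_rounded"] = round(
                st.coding_fraction_percent, 1
            )
            observed["yp_sas_upstream_2mm"] = sum(
                1 for _, c in classified2 if c.category == "upstream"
            )
            observed["yp_sas_intragenic_2mm"] = sum(
                1 for _, c in classified2 if c.category == "intragenic"
            )
            esas_annotated = associate_with_sas(esas, hits2, proximity)
            esas_annotated = flag_start_codon_coincidence(esas_annotated, features)
            observed["yp_esas_total"] = len(esas_annotated)
            observed["yp_esas_sas_associated"] = sum(
                1 for e in esas_annotated if e.associated_sas is not None
            )
            observed["yp_esas_boundary_coincident"] = sum(
                1 for e in esas_annotated if e.start_codon_coincident
            )
        if acc == "MZ274310":
            observed["k8_sas_total_2mm"] = len(hits2)
    observed["panel_sas_total_2mm"] = sas2_total
    observed["panel_sas_intra_orf_2mm"] = intra2_total
    observed["panel_sas_exactly_3mm"] = sas3_total
    observed["panel_esas_total"] = esas_total
    return observed


def match_report(observed: dict[str, float]) -> pd.DataFrame:
    """Target-by-target comparison with the published values."""
    rows = [
        {
            "target": key,
            "expected": expected,
            "observed": observed.get(key),
            "match": observed.get(key) == expected,
        }
        for key, expected in EXPECTED.items()
    ]
    return pd.DataFrame(rows)
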