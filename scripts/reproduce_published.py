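"""Fetch the eight representative cluster K GenBank records and reproduce
the published panel numbers.

Needs network access for the fetch step (NCBI E-utilities via Biopython's
Entrez); once the records are cached under data/genbank/ the reproduction
itself runs offline.

Usage:
    python scripts/reproduce_published.py [--genbank-dir data/genbank]
        [--out results/reproduction_report.tsv] [--email you@example.org]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

from kmotif.reproduce import PANEL, match_report, reproduce_panel


def fetch_records(genbank_dir: Path, email: str) -> None:
    from Bio import Entrez

    Entrez.email = email
    genbank_dir.mkdir(parents=True, exist_ok=True)
    for acc in PANEL:
        target = genbank_dir / f"{acc}.gb"
        if target.exists():
            print(f"cached: {target}", file=sys.stderr)
            continue
        print(f"fetching {acc} ...", file=sys.stderr)
        with Entrez.efetch(db="nuccore", id=acc, rettype="gbwithparts",
                           retmode="text") as handle:
            target.write_text(handle.read())


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--genbank-dir", type=Path, default=Path("data/genbank"))
    ap.add_argument("--out", type=Path, default=Path("results/reproduction_report.tsv"))
    ap.add_argument("--email", default="kmotif@example.org",
                    help="contact email NCBI requires for E-utilities")
    ap.add_argument("--no-fetch", action="store_true",
                    help="use only records already on disk")
    args = ap.parse_args()

    if not args.no_fetch:
        fetch_records(args.genbank_dir, args.email)

    observed = reproduce_panel(args.genbank_dir)
    report = match_report(observed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(args.out, sep="\t", index=False)
    print(report.to_string(index=False))
    if not report["match"].all():
        print("\nsome targets did not reproduce; see report", file=sys.stderr)
        sys.exit(1)


if __name__ == "__main__":
    main()
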