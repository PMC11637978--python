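#!/usr/bin/env python
"""Helicase signature-motif screen.

Scans protein sequences for the 8 DDX, 8 DHX and 3 other helicase consensus
motifs.  By default the screen runs on seeded synthetic sequences with known
planted motifs (verifying recovery); pass ``--fasta`` to screen a real
protein, e.g. a user-supplied LRPPRC sequence (UniProt P42704), which is
expected to yield zero hits.
"""

import argparse
from pathlib import Path

import pandas as pd

from mitoribo import motif_scan as ms, synthetic_data as sd
from mitoribo.io_formats import read_fasta


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--fasta", type=Path, default=None,
                    help="screen this FASTA instead of the planted fixture")
    ap.add_argument("--out", type=Path, default=Path("results/05_motifs"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    if args.fasta:
        records = read_fasta(args.fasta)
        truth = None
    else:
        plants = [("PTRELA", 10), ("DExD", 100), ("GFxxPxxIQ", 42), ("AHTSAGKT", 150)]
        records, truth = sd.planted_motif_sequences(seed=args.seed, plants=plants, length=220)

    matches = ms.scan_all(records)
    pd.DataFrame(
        [(m.seq_id, m.motif, m.family, m.position, m.substring) for m in matches],
        columns=["seq_id", "motif", "family", "position", "substring"],
    ).to_csv(args.out / "motif_hits.tsv", sep="\t", index=False)

    report = ms.helicase_report(matches)
    print(f"Scanned {len(records)} sequence(s) against 19 motifs "
          f"(8 DDX, 8 DHX, 3 other): {report['n_matches']} hit(s).")
    print(f"Verdict: {report['verdict']}")
    if truth is not None:
        found = {(m.seq_id, m.motif, m.position) for m in matches}
        missing = [t for t in truth if t not in found]
        print(f"Planted motifs recovered: {len(truth) - len(missing)}/{len(truth)}")
    print(f"Hits table in {args.out}/motif_hits.tsv")


if __name__ == "__main__":
    main()
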