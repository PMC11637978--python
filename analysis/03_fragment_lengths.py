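#!/usr/bin/env python
"""Protected-fragment length distributions, KO versus rescue.

After soft-clip removal, tallies mitoribosome-protected fragment lengths for
reads mapping to mitochondrial mRNAs and compares the count-weighted mean
length between conditions (the KO libraries are generated with a 2 nt
shorter mean protected fragment).
"""

import argparse
from itertools import chain
from pathlib import Path

from mitoribo import counting, synthetic_data as sd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-reads", type=int, default=100_000)
    ap.add_argument("--out", type=Path, default=Path("results/03_lengths"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    annotation = sd.make_mito_annotation()
    preset = sd.default_ko_preset()
    specs = [s for s in sd.library_specs_for_contrast(n_reads=args.n_reads, seed=args.seed)
             if s.assay == "RPF"]
    stream = chain.from_iterable(sd.sample_library(s, annotation, preset) for s in specs)
    dist = counting.length_distribution(stream, annotation, target_only=True)

    long = dist.counts.stack().rename("count").reset_index()
    long.columns = ["length", "library_id", "count"]
    frac = dist.fractions().stack().rename("fraction").reset_index()
    long["fraction"] = frac["fraction"]
    long.to_csv(args.out / "length_distribution.tsv", sep="\t", index=False)

    means = {lib: counting.mean_protected_length(dist, lib) for lib in dist.counts.columns}
    print(f"Mean protected-fragment length over mito mRNAs ({args.n_reads} RPF reads each):")
    for lib, m in means.items():
        print(f"  {lib}: {m:.2f} nt")
    print(f"KO fragments are {means['rpf_rescue'] - means['rpf_KO']:.2f} nt shorter "
          "than rescue on average.")
    print(f"Table in {args.out}/length_distribution.tsv")


if __name__ == "__main__":
    main()
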