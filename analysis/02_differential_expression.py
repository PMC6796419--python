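"""Run the five differential-expression contrasts.

Median-of-ratios size factors are estimated once on the full matrix; each
contrast then applies its own zero-count filter (50%-per-group for the large
contrasts, absolute zero budgets for the tiny ones) and fits the NB Wald
model with age and sex adjustment.  Writes one DESeq2-style table per
analysis under results/de/.
"""

import argparse
from pathlib import Path

from crosscontrast.counts_io import (STUDY_CONTRASTS, compute_size_factors,
                                     read_counts, read_metadata)
from crosscontrast.diffexp import run_contrast, write_de_table


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/de"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    counts = read_counts(args.datadir / "counts.tsv")
    meta = read_metadata(args.datadir / "metadata.tsv")
    size_factors = compute_size_factors(counts)
    size_factors.to_csv(args.outdir / "size_factors.tsv", sep="\t", header=True)

    for label, spec in STUDY_CONTRASTS.items():
        de = run_contrast(counts, meta, spec, size_factors=size_factors)
        write_de_table(de, args.outdir / f"analysis_{label}.tsv")
        n_sig = int((de["padj"] < 0.05).sum())
        print(f"analysis ({label}): n={int(de['n_total'].iloc[0]):3d} samples, "
              f"{len(de)} genes detected, {n_sig} DE at FDR<0.05")


if __name__ == "__main__":
    main()
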