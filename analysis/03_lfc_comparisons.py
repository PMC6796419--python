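"""Confidence-adjusted comparison of fold changes across contrasts.

Two Welch comparisons: (3) vs (5) separates disease-driven caudate changes
from ordinary region differences; (1) vs (2) contrasts the symptomatic and
asymptomatic cortex responses and feeds the early/late-responder partition
with its quadrant labels.  Writes tables under results/compare/ and reports
how many true interaction genes the (3)-vs-(5) statistic recovers.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from crosscontrast.diffexp import read_de_table
from crosscontrast.lfc_ttest import (partition_early_late, rank_by_t,
                                     welch_compare)


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--dedir", type=Path, default=Path("results/de"))
    parser.add_argument("--outdir", type=Path, default=Path("results/compare"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    de = {label: read_de_table(args.dedir / f"analysis_{label}.tsv")
          for label in ("1", "2", "3", "5")}

    welch_35 = welch_compare(de["3"], de["5"])
    welch_35.to_csv(args.outdir / "welch_3v5.tsv", sep="\t", index_label="gene_id")
    ranking = rank_by_t(welch_35)
    ranking.to_csv(args.outdir / "ranking_3v5.tsv", sep="\t", header=True,
                   index_label="gene_id")
    n_sig = int((welch_35["pvalue"] < 0.05).sum())
    print(f"(3) vs (5): {len(welch_35)} genes compared, {n_sig} significant "
          f"between (raw p<0.05), median df {welch_35['df'].median():.1f}")

    truth_path = args.datadir / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col=0)
        inter = [g for g in truth.index[truth["is_interaction"]]
                 if g in welch_35.index and np.isfinite(welch_35.loc[g, "t"])]
        sens = (welch_35.loc[inter, "pvalue"] < 0.05).mean()
        print(f"  recovered {sens:.1%} of {len(inter)} true interaction genes")

    welch_12 = welch_compare(de["1"], de["2"])
    welch_12.to_csv(args.outdir / "welch_1v2.tsv", sep="\t", index_label="gene_id")
    part = partition_early_late(de["1"], de["2"], welch_12)
    part["genes"].to_csv(args.outdir / "early_late_genes.tsv", sep="\t",
                         index_label="gene_id")
    part["table"].to_csv(args.outdir / "early_late_table.tsv", sep="\t",
                         header=True)
    quad = part["genes"].loc[part["genes"]["quadrant"] != "", "quadrant"]
    print(f"(1) vs (2): early/late partition over {part['table'].sum()} genes; "
          f"quadrant counts {quad.value_counts().to_dict()}")


if __name__ == "__main__":
    main()
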