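"""Preranked GSEA for the three disease contrasts and the (3)-vs-(5) ranking.

Analyses (1), (2) and (4) are ranked by descending log2 fold change; the
(3)-vs-(5) comparison by descending Welch t.  Writes one result table per
ranking under results/gsea/ and reports detection of the truly enriched
synthetic sets.
"""

import argparse
from pathlib import Path

import pandas as pd

from crosscontrast.diffexp import read_de_table
from crosscontrast.gene_sets import read_gmt
from crosscontrast.gsea import preranked_gsea, rank_by_score, write_gsea_table
from crosscontrast.lfc_ttest import rank_by_t
from crosscontrast.pipeline import stage_seed


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-perm", type=int, default=2000)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--dedir", type=Path, default=Path("results/de"))
    parser.add_argument("--comparedir", type=Path, default=Path("results/compare"))
    parser.add_argument("--outdir", type=Path, default=Path("results/gsea"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sets = read_gmt(args.datadir / "gene_sets.gmt")
    rankings = {}
    for label in ("1", "2", "4"):
        de = read_de_table(args.dedir / f"analysis_{label}.tsv")
        rankings[label] = rank_by_score(de["log2FoldChange"].dropna())
    welch = pd.read_csv(args.comparedir / "welch_3v5.tsv", sep="\t", index_col=0)
    rankings["3v5"] = rank_by_t(welch)

    for i, (label, ranking) in enumerate(rankings.items()):
        res = preranked_gsea(ranking, sets, n_perm=args.n_perm,
                             seed=stage_seed(args.seed, 10 + i))
        write_gsea_table(res, args.outdir / f"analysis_{label}.tsv")
        sig = res["padj"] < 0.05
        truly = res.index.str.startswith("ENRSET")
        print(f"analysis {label}: {int(sig.sum())}/{len(res)} sets enriched at "
              f"FDR<0.05 ({int((sig & truly).sum())} of the {int(truly.sum())} "
              f"truly enriched)")


if __name__ == "__main__":
    main()
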